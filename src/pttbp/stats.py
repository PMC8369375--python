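"""Agreement metrics, device grading, and the comparison-test battery.

Estimated-vs-reference BP agreement is summarized by the mean absolute
difference (MAD), RMSE, Pearson correlation, and Bland-Altman bias with
1.96*SD limits; the MAD maps to a wearable-cuffless-device grade (A <= 5,
B <= 6, C <= 7 mm Hg, else D).  Demographic coefficient comparisons follow
the study's routing: a one-sample Kolmogorov-Smirnov normality check per
group, then a Mann-Whitney U test for unpaired groupings (obesity, sex,
race, age) or a Wilcoxon signed-rank test for paired ones (PPG
wavelengths).  Small tie-free samples use exact enumeration p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_GRADE_THRESHOLDS_MM_HG = {"A": 5.0, "B": 6.0, "C": 7.0}

#: sample-size limit below which tie-free rank tests use exact enumeration
EXACT_N_LIMIT = 12


@dataclass
class AgreementReport:
    component: str
    n: int
    mad: float
    rmse: float
    pcc: float  # nan when either side is constant
    bias: float
    loa_low: float
    loa_high: float

    @property
    def loa_width(self) -> float:
        return self.loa_high - self.loa_low

    @property
    def loa_half_width(self) -> float:
        return 0.5 * self.loa_width

    @property
    def pcc_defined(self) -> bool:
        return np.isfinite(self.pcc)


@dataclass
class GroupComparison:
    grouping: str
    coefficient: str
    group_names: tuple[str, str]
    group_n: tuple[int, int]
    group_mean: tuple[float, float]
    group_sd: tuple[float, float]
    normal: tuple[bool, bool]
    test: str
    statistic: float
    p: float
    groups: dict = field(default_factory=dict, repr=False)

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def agreement_metrics(estimated, reference, component: str = "") -> AgreementReport:
    """MAD, RMSE, PCC, and Bland-Altman bias +/- 1.96 SD limits of agreement."""
    est = np.asarray(estimated, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValueError("estimated and reference must be equal-length 1-D sequences")
    if len(est) < 2:
        raise ValueError("need at least 2 pairs")
    diff = est - ref
    mad = float(np.mean(np.abs(diff)))
    rmse = float(np.sqrt(np.mean(diff**2)))
    if np.ptp(est) == 0 or np.ptp(ref) == 0:
        pcc = float("nan")
    else:
        pcc = float(np.corrcoef(est, ref)[0, 1])
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return AgreementReport(
        component=component,
        n=len(est),
        mad=mad,
        rmse=rmse,
        pcc=pcc,
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
    )


def ieee_grade(mad_mm_hg: float, thresholds: dict[str, float] | None = None) -> str:
    """Map a MAD (mm Hg) to the wearable cuffless-device grade A/B/C/D."""
    if mad_mm_hg < 0:
        raise ValueError("MAD must be non-negative")
    th = thresholds or DEFAULT_GRADE_THRESHOLDS_MM_HG
    for grade in ("A", "B", "C"):
        if mad_mm_hg <= th[grade]:
            return grade
    return "D"


def _has_ties(*samples) -> bool:
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    return len(np.unique(pooled)) < len(pooled)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (Wilcoxon rank-sum).

    Exact enumeration when n_x + n_y <= 12 with no ties; otherwise the
    normal approximation with tie correction and continuity correction.
    Returns (U of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    exact = len(x) + len(y) <= EXACT_N_LIMIT and not _has_ties(x, y)
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(differences) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank on paired differences.

    Zeros are discarded first; exact sign-pattern enumeration for n <= 12
    (tie-free), else the normal approximation.  Raises on all-zero input.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("degenerate: all differences are zero")
    exact = len(d) <= EXACT_N_LIMIT and not _has_ties(np.abs(d))
    res = sps.wilcoxon(d, alternative="two-sided", method="exact" if exact else "approx")
    return float(res.statistic), float(res.pvalue)


def ks_normality(x, alpha: float = 0.05, lilliefors: bool = False) -> tuple[float, float, bool]:
    """One-sample KS test against a normal law with sample-estimated moments.

    Returns (D, p, normal at ``alpha``).  The default p comes from the
    standard KS distribution (the study's procedure); ``lilliefors=True``
    applies the correction appropriate for estimated parameters.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise ValueError("need n >= 4 for the normality check")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: normality test undefined")
    if lilliefors:
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

        d, p = sm_lilliefors(x, dist="norm")
    else:
        d, p = sps.kstest(x, "norm", args=(np.mean(x), np.std(x, ddof=1)))
    return float(d), float(p), bool(p >= alpha)


def t_test_two_sample(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Unpaired two-tailed pooled-variance t test from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# demographic comparisons

GROUPINGS = {
    "obesity": ("nonobese", "obese"),
    "sex": ("male", "female"),
    "race": ("other", "Black"),
    "age": ("young", "older"),
}


def _assign_group(row: pd.Series, grouping: str) -> str | None:
    if grouping == "obesity":
        return "obese" if row["bmi"] >= 30.0 else "nonobese"
    if grouping == "sex":
        return row["sex"]
    if grouping == "race":
        return "Black" if row["race"] == "Black" else "other"
    if grouping == "age":
        # the study brackets are "<= 40" and ">= 40"; exactly 40 goes to older
        return "older" if row["age"] >= 40.0 else "young"
    raise ValueError(f"unknown grouping {grouping!r} (choose from {sorted(GROUPINGS)})")


def compare_groups(
    table: pd.DataFrame,
    grouping: str,
    coefficient: str = "K1_DBP",
    min_per_group: int = 3,
) -> GroupComparison:
    """Stratify a coefficient table by a demographic factor and test the
    group difference.

    ``table`` needs one row per participant with the coefficient column and
    the demographic columns (bmi / sex / race / age).  Both groups get a
    KS normality check; these groupings are unpaired so the difference is
    tested with Mann-Whitney U (the routing the normality outcomes justify
    on this kind of skewed coefficient data).
    """
    if coefficient not in table.columns:
        raise ValueError(f"table has no column {coefficient!r}")
    names = GROUPINGS[grouping] if grouping in GROUPINGS else None
    labels = table.apply(_assign_group, axis=1, grouping=grouping)
    groups = {}
    for name in names or sorted(labels.dropna().unique()):
        vals = table.loc[labels == name, coefficient].to_numpy(dtype=float)
        groups[name] = vals
    if len(groups) != 2:
        raise ValueError(f"grouping {grouping!r} must yield two groups, got {list(groups)}")
    (name_a, a), (name_b, b) = groups.items()
    if len(a) < min_per_group or len(b) < min_per_group:
        raise ValueError(
            f"need >= {min_per_group} participants per group "
            f"(got {name_a}: {len(a)}, {name_b}: {len(b)})"
        )

    def normal_or_false(v: np.ndarray) -> bool:
        try:
            return ks_normality(v)[2]
        except ValueError:
            return False

    u, p = mann_whitney_u(a, b)
    return GroupComparison(
        grouping=grouping,
        coefficient=coefficient,
        group_names=(name_a, name_b),
        group_n=(len(a), len(b)),
        group_mean=(float(np.mean(a)), float(np.mean(b))),
        group_sd=(float(np.std(a, ddof=1)), float(np.std(b, ddof=1))),
        normal=(normal_or_false(a), normal_or_false(b)),
        test="mann_whitney_u",
        statistic=u,
        p=p,
        groups={name_a: a, name_b: b},
    )


def compare_wavelengths_paired(per_participant: pd.DataFrame, metric_cols: tuple[str, str]) -> tuple[float, float]:
    """Paired comparison of two per-participant wavelength metrics
    (e.g. DBP correlation with green vs IR) via Wilcoxon signed-rank."""
    a, b = (per_participant[c].to_numpy(dtype=float) for c in metric_cols)
    return wilcoxon_signed_rank(a - b)
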