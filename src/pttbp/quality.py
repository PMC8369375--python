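"""SNR scoring, PPG beat selection, and per-task quality gating.

An ensemble window's SNR compares the power of the averaged beat (signal)
with the power of the member residuals about that average (noise).  Per
task, the PPG ensemble is chosen by a physiologically motivated rule: pool
the windows with the top 10 % of systolic upstrokes (maximum first
derivative) and take the pool member with the highest SNR.  The reference
ABP ensemble is simply the highest-SNR window.  A task is kept only when
the SCG, PPG, and ABP SNRs all reach the participant-specific thresholds
and the PPG foot (as a pulse-arrival time from the R-wave) falls in a
realistic range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from pttbp.beats import EnsembleBeat

SNR_CAP_DB = 60.0


@dataclass
class SnrThresholds:
    """Per-channel minimum SNR (dB) and the allowed PAT window (s)."""

    ppg_db: float = -np.inf
    scg_db: float = -np.inf
    abp_db: float = -np.inf
    foot_range_s: tuple[float, float] = (0.10, 0.50)

    def __post_init__(self) -> None:
        lo, hi = self.foot_range_s
        if hi <= lo:
            raise ValueError(f"foot_range_s must have positive width, got ({lo}, {hi})")


@dataclass
class TaskSelection:
    """Chosen PPG/SCG/ABP ensembles for one task plus the gate outcome."""

    task: str
    ppg: EnsembleBeat
    scg: EnsembleBeat
    abp: EnsembleBeat
    wavelength: str
    kept: bool = True
    reasons: list[str] = field(default_factory=list)


def compute_snr(members: list[np.ndarray], averaged: np.ndarray, cap_db: float = SNR_CAP_DB) -> float:
    """SNR_dB = 10 log10(P_signal / P_noise), capped at ``cap_db``.

    P_signal is the mean power of the averaged beat; P_noise the mean power
    of the member residuals about that average.
    """
    if len(members) < 2:
        raise ValueError("need >= 2 member beats")
    m = min(len(b) for b in members)
    m = min(m, len(averaged))
    stacked = np.stack([np.asarray(b[:m], dtype=float) for b in members])
    avg = np.asarray(averaged[:m], dtype=float)
    p_signal = float(np.mean(avg**2))
    p_noise = float(np.mean((stacked - avg) ** 2))
    if p_signal == 0 and p_noise == 0:
        raise ValueError("zero-power window")
    if p_noise == 0:
        return cap_db
    snr = 10.0 * math.log10(p_signal / p_noise) if p_signal > 0 else -cap_db
    return min(snr, cap_db)


def score_ensembles(ensembles: list[EnsembleBeat]) -> None:
    """Fill ``snr_db`` on each ensemble in place (members must be retained)."""
    for e in ensembles:
        e.snr_db = compute_snr(e.members, e.samples)


def max_upstroke(samples: np.ndarray, fs: float) -> float:
    """Maximum first derivative (units/s) — the systolic-upstroke score."""
    return float(np.max(np.diff(samples)) * fs)


def select_ppg_ensemble(ensembles: list[EnsembleBeat]) -> int:
    """Top-10 %-upstroke pool, then maximum SNR; ties go to the earlier window."""
    if not ensembles:
        raise ValueError("empty ensemble list")
    if any(e.snr_db is None for e in ensembles):
        raise ValueError("SNRs must be computed before selection")
    m = len(ensembles)
    pool_size = max(1, math.ceil(0.1 * m))
    upstrokes = np.array([max_upstroke(e.samples, e.fs) for e in ensembles])
    # stable sort descending: ties keep earlier windows first
    pool = list(np.argsort(-upstrokes, kind="stable")[:pool_size])
    snrs = np.array([ensembles[i].snr_db for i in pool])
    return int(pool[int(np.argmax(snrs))])


def select_reference_bp(ensembles: list[EnsembleBeat]) -> int:
    """Index of the maximum-SNR ABP ensemble; ties go to the earlier window."""
    if not ensembles:
        raise ValueError("empty ensemble list")
    snrs = np.array([e.snr_db for e in ensembles], dtype=float)
    return int(np.argmax(snrs))


def gate_task(selection: TaskSelection, thresholds: SnrThresholds, ppg_foot_s: float) -> TaskSelection:
    """Keep a task iff all three SNRs reach their thresholds and the PPG foot
    (as PAT from the beat-start R-wave) lies inside ``foot_range_s``.

    The outcome and machine-readable drop reasons are written back onto the
    selection.  Gating is monotone: raising any threshold never converts a
    dropped task to kept.
    """
    reasons = []
    if not selection.scg.snr_db >= thresholds.scg_db:
        reasons.append("scg_snr")
    if not selection.ppg.snr_db >= thresholds.ppg_db:
        reasons.append("ppg_snr")
    if not selection.abp.snr_db >= thresholds.abp_db:
        reasons.append("abp_snr")
    lo, hi = thresholds.foot_range_s
    if not (lo <= ppg_foot_s <= hi):
        reasons.append("foot_range")
    selection.kept = not reasons
    selection.reasons = reasons
    return selection


#: absolute per-channel SNR floors (dB): a window below these is unusable no
#: matter how the rest of the recording looks
DEFAULT_SNR_FLOORS_DB = {"ppg": 5.0, "scg": 0.0, "abp": 20.0}


def participant_thresholds(
    snrs_by_channel: dict[str, list[float]],
    quantile: float = 0.25,
    foot_range_s: tuple[float, float] = (0.10, 0.50),
    floors_db: dict[str, float] | None = None,
) -> SnrThresholds:
    """Participant-specific thresholds: the larger of an absolute per-channel
    floor and a low quantile of that participant's own window SNRs, so a
    uniformly clean recording keeps everything while a uniformly noisy one
    keeps only its best windows (down to the floor)."""
    floors = dict(DEFAULT_SNR_FLOORS_DB, **(floors_db or {}))

    def q(name: str) -> float:
        vals = snrs_by_channel.get(name, [])
        quant = float(np.quantile(vals, quantile)) if vals else -np.inf
        return max(quant, floors.get(name, -np.inf))

    return SnrThresholds(
        ppg_db=q("ppg"), scg_db=q("scg"), abp_db=q("abp"), foot_range_s=foot_range_s
    )
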