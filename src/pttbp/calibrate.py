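"""Per-participant calibration of the conventional PTT model.

BP relates to pulse transit time through ``BP = K1 / PTT + K2``: ordinary
least squares of the reference BP on inverse PTT gives the slope K1
(mm Hg*s) and intercept K2 (mm Hg) per BP component.  At least four
(task-level) calibration points are required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BP_COMPONENTS = ("DBP", "MAP", "SBP")


class CalibrationError(Exception):
    pass


@dataclass
class CalibrationPoint:
    """One kept task: its measured PTT paired with the reference BP triple."""

    task: str
    ptt_s: float
    dbp: float
    map_: float
    sbp: float

    def __post_init__(self) -> None:
        if self.ptt_s <= 0:
            raise ValueError(f"task {self.task!r}: non-positive PTT")
        if not self.dbp <= self.map_ <= self.sbp:
            raise ValueError(
                f"task {self.task!r}: BP ordering violated ({self.dbp}, {self.map_}, {self.sbp})"
            )

    def bp(self, component: str) -> float:
        return {"DBP": self.dbp, "MAP": self.map_, "SBP": self.sbp}[component]


@dataclass
class CalibrationModel:
    component: str
    k1: float  # mm Hg*s
    k2: float  # mm Hg
    n_points: int
    residual_rms: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.k1) and np.isfinite(self.k2)):
            raise ValueError("non-finite calibration coefficients")


def fit_calibration(
    points: list[CalibrationPoint], component: str, min_points: int = 4
) -> CalibrationModel:
    """OLS of BP on PTT^-1; K1 = slope, K2 = intercept.

    Raises :class:`CalibrationError` with "insufficient tasks" for fewer
    than ``min_points`` points, or on a degenerate PTT spread.
    """
    if component not in BP_COMPONENTS:
        raise ValueError(f"unknown BP component {component!r}")
    if len(points) < min_points:
        raise CalibrationError(
            f"insufficient tasks: {len(points)} calibration points < {min_points}"
        )
    x = np.array([1.0 / p.ptt_s for p in points])
    y = np.array([p.bp(component) for p in points])
    if np.ptp(x) < 1e-9 * max(1.0, abs(x[0])):
        raise CalibrationError("degenerate PTT spread: all points share one PTT")
    design = np.column_stack([x, np.ones_like(x)])
    (k1, k2), *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - (k1 * x + k2)
    return CalibrationModel(
        component=component,
        k1=float(k1),
        k2=float(k2),
        n_points=len(points),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def estimate_bp(model: CalibrationModel, ptt_s: float) -> float:
    """BP = K1 / PTT + K2 (mm Hg)."""
    if ptt_s <= 0:
        raise ValueError(f"PTT must be positive, got {ptt_s}")
    return model.k1 / ptt_s + model.k2
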