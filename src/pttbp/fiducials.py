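"""Fiducial detection and pulse transit time.

The distal timing reference is the PPG diastolic foot, located with the
intersecting-tangent construction: the tangent at the point of maximum
first derivative on the systolic upstroke is intersected with the
horizontal line through the preceding local minimum.  The proximal
reference is the SCG aortic-valve-opening (AO) point, taken as the
earliest sufficiently prominent local maximum inside a physiologic
pre-ejection-period window before the PPG foot.  PTT = foot - AO; the
pulse arrival time (PAT) is the foot time from the beat-start R-wave,
so PAT = PEP + PTT.

Both detectors are time-shift equivariant and amplitude-scale invariant;
sub-sample resolution comes from exact line algebra (foot) and parabolic
peak interpolation (AO).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

DEFAULT_PEP_RANGE_S = (0.03, 0.15)
DEFAULT_PROMINENCE_FRACTION = 0.10


class FiducialError(Exception):
    """Raised when a fiducial cannot be located on a beat."""


@dataclass
class FiducialResult:
    """Per-task fiducial timings, seconds from the beat-start R-wave."""

    foot_time_s: float
    ao_time_s: float
    wavelength: str = "ppg_ir"
    pep_range_s: tuple[float, float] = DEFAULT_PEP_RANGE_S

    @property
    def ptt_s(self) -> float:
        return self.foot_time_s - self.ao_time_s

    @property
    def pat_s(self) -> float:
        return self.foot_time_s


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-sample offset of the extremum of a parabola through y[i-1:i+2]."""
    if i <= 0 or i >= len(y) - 1:
        return 0.0
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0:
        return 0.0
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(np.clip(delta, -0.5, 0.5))


def ppg_foot_intersecting_tangent(beat: np.ndarray, fs: float) -> float:
    """Diastolic-foot time (s from beat start) by the intersecting-tangent method.

    The result may fall between samples.  Raises :class:`FiducialError` when
    the beat has no rising edge or its derivative maximum sits on the beat
    boundary (no tangent can be formed).
    """
    x = np.asarray(beat, dtype=float)
    if len(x) < 5:
        raise FiducialError(f"beat too short ({len(x)} samples)")
    # centered first difference; d[i] approximates the slope at sample i
    d = np.empty(len(x))
    d[1:-1] = 0.5 * (x[2:] - x[:-2])
    d[0], d[-1] = x[1] - x[0], x[-1] - x[-2]
    i = int(np.argmax(d))
    if d[i] <= 0:
        raise FiducialError("no rising edge on beat")
    if i == 0 or i == len(x) - 1:
        raise FiducialError("derivative maximum at beat boundary")
    # sub-sample tangent point: parabolic apex of the derivative
    delta = _parabolic_refine(d, i)
    slope = (d[i] + 0.5 * delta * (d[i + 1] - d[i - 1])) * fs
    t_tan = (i + delta) / fs
    # value at the tangent point (quadratic interpolation is overkill here:
    # the slope is locally stationary, linear interpolation suffices)
    v_tan = np.interp(i + delta, np.arange(len(x)), x)
    # preceding local minimum: nearest sample before the tangent point that
    # is <= both neighbours; fall back to the global minimum of the prefix
    j = None
    for k in range(i, 0, -1):
        if x[k] <= x[k - 1] and (k == len(x) - 1 or x[k] <= x[k + 1]):
            j = k
            break
    if j is None:
        j = int(np.argmin(x[: i + 1]))
    baseline = x[j]
    foot = t_tan - (v_tan - baseline) / slope
    return float(foot)


def ao_candidates(
    scg_beat: np.ndarray,
    fs: float,
    foot_time_s: float,
    pep_range_s: tuple[float, float] = DEFAULT_PEP_RANGE_S,
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
) -> list[float]:
    """All qualifying AO candidate times, earliest first.

    Qualifying peaks are local maxima of the SCG beat with prominence above
    ``prominence_fraction`` of the beat's peak-to-peak amplitude and time in
    ``[pep_lo, min(pep_hi, foot))``.
    """
    x = np.asarray(scg_beat, dtype=float)
    lo, hi = pep_range_s
    if lo <= 0 or pep_range_s[1] <= lo:
        raise ValueError(f"invalid pep_range {pep_range_s}")
    hi = min(hi, foot_time_s)
    if hi <= lo:
        raise FiducialError(
            f"PPG foot at {foot_time_s:.3f} s precedes the PEP window start {lo:.3f} s"
        )
    p2p = float(np.ptp(x))
    if p2p == 0:
        return []
    peaks, _ = sp_signal.find_peaks(x, prominence=prominence_fraction * p2p)
    times = []
    for p in peaks:
        t = (p + _parabolic_refine(x, p)) / fs
        if lo <= t < hi:
            times.append(float(t))
    return times


def detect_ao(
    scg_beat: np.ndarray,
    fs: float,
    foot_time_s: float,
    pep_range_s: tuple[float, float] = DEFAULT_PEP_RANGE_S,
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
    prefer_latency_s: float | None = None,
) -> float:
    """AO time: the earliest qualifying SCG peak before the PPG foot.

    With ``prefer_latency_s`` set (consistent-morphology mode), the
    candidate closest to that latency is returned instead, so the same
    morphological peak is chosen across a participant's tasks.
    """
    candidates = ao_candidates(scg_beat, fs, foot_time_s, pep_range_s, prominence_fraction)
    if not candidates:
        raise FiducialError(
            f"no qualifying SCG peak in [{pep_range_s[0]}, {min(pep_range_s[1], foot_time_s)}) s"
        )
    if prefer_latency_s is not None:
        return min(candidates, key=lambda t: abs(t - prefer_latency_s))
    return candidates[0]


def compute_ptt(ao_time_s: float, foot_time_s: float) -> float:
    """PTT = foot - AO (s); both times share the beat-start origin."""
    ptt = foot_time_s - ao_time_s
    if ptt <= 0:
        raise FiducialError(f"non-positive PTT: foot {foot_time_s} <= ao {ao_time_s}")
    return float(ptt)
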