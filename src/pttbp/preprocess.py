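"""Stream alignment and filtering.

The processing front end mirrors the device's published chain: both ECGs are
band-passed 10-40 Hz and R-peaks detected; the two streams are aligned by
cross-correlating their R-peak trains; the SCG is band-passed 1-40 Hz, the
PPGs 1-8 Hz, and the continuous ABP smoothed with a 50 ms moving average.

All band-pass filtering is linear-phase FIR (Hamming windowed sinc) with the
group delay compensated, so fiducial timings are unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, signal

DEFAULT_BANDS = {
    "ecg": (10.0, 40.0),
    "scg": (1.0, 40.0),
    "ppg": (1.0, 8.0),
}
ABP_SMOOTH_MS = 50.0


class AlignmentError(Exception):
    """Raised when the cross-correlation lag between the two ECGs is ambiguous."""


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass FIR (f_lo/f_hi) or moving-average (window_ms) description."""

    f_lo: float = 1.0
    f_hi: float = 8.0
    kind: str = "bandpass_fir"  # or "moving_average"
    window_ms: float = ABP_SMOOTH_MS

    def validate(self, fs: float) -> None:
        if self.kind == "bandpass_fir":
            if not (0 < self.f_lo < self.f_hi < fs / 2):
                raise ValueError(
                    f"invalid band [{self.f_lo}, {self.f_hi}] Hz for fs={fs} Hz"
                )
        elif self.kind == "moving_average":
            if self.window_ms <= 0:
                raise ValueError("window_ms must be positive")
        else:
            raise ValueError(f"unknown filter kind {self.kind!r}")


def fir_order(f_lo: float, fs: float, max_order: int = 4000) -> int:
    """Windowed-sinc order: min(4*fs/f_lo rounded to even, max_order).

    Four cycles of the low edge keep the Hamming transition band narrower
    than the edge frequency itself, which is what pushes DC and sub-band
    respiration/postural drift into the stop band.
    """
    order = int(round(4.0 * fs / f_lo / 2.0)) * 2
    return min(order, max_order)


def design_bandpass(spec: FilterSpec, fs: float) -> np.ndarray:
    spec.validate(fs)
    order = fir_order(spec.f_lo, fs)
    # odd tap count -> type-I linear phase, integer group delay order/2
    taps = signal.firwin(order + 1, [spec.f_lo, spec.f_hi], pass_zero=False, fs=fs)
    # zero the residual DC gain exactly (perturbs the passband by < 1e-4)
    return taps - taps.mean()


def bandpass_fir(x: np.ndarray, fs: float, spec: FilterSpec) -> np.ndarray:
    """Apply a linear-phase band-pass FIR with the group delay removed.

    The output has the same length as the input; interior samples are the
    zero-phase response, so symmetric waveform features keep their timing.
    """
    x = np.asarray(x, dtype=float)
    taps = design_bandpass(spec, fs)
    if len(x) <= len(taps):
        raise ValueError(f"signal length {len(x)} <= filter length {len(taps)}")
    delay = (len(taps) - 1) // 2
    full = signal.fftconvolve(x, taps, mode="full")
    return full[delay : delay + len(x)]


def smooth_moving_average(x: np.ndarray, fs: float, window_ms: float = ABP_SMOOTH_MS) -> np.ndarray:
    """Centered moving mean; edge windows shrink to the available samples."""
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("empty signal")
    n = max(1, int(round(window_ms * fs / 1000.0)))
    kernel = np.ones(n)
    # centered placement; for even n the window extends one sample further left
    left = n // 2
    sums = signal.fftconvolve(x, kernel, mode="full")[left : left + len(x)]
    counts = np.convolve(np.ones(len(x)), kernel, mode="full")[left : left + len(x)]
    return sums / counts


def detect_r_peaks(
    ecg: np.ndarray,
    fs: float,
    raw: bool = False,
    refractory_s: float = 0.25,
    threshold_fraction: float = 0.5,
    rolling_window_s: float = 2.0,
) -> np.ndarray:
    """R-peak times (s) via an adaptive-threshold local-maximum detector.

    The threshold tracks ``threshold_fraction`` times the rolling 2 s maximum
    of the (10-40 Hz filtered) ECG; a 250 ms refractory period supports
    heart rates up to 240 bpm.  Pass ``raw=True`` for an unfiltered trace.
    """
    ecg = np.asarray(ecg, dtype=float)
    if raw:
        ecg = bandpass_fir(ecg, fs, FilterSpec(*DEFAULT_BANDS["ecg"]))
    if not np.any(ecg > 0):
        raise ValueError("no peaks found: signal has no positive excursion")
    win = max(1, int(round(rolling_window_s * fs)))
    rolling_max = ndimage.maximum_filter1d(ecg, size=win, mode="nearest")
    height = threshold_fraction * rolling_max
    distance = max(1, int(round(refractory_s * fs)))
    peaks, _ = signal.find_peaks(ecg, height=height, distance=distance)
    if len(peaks) == 0:
        raise ValueError("no peaks found")
    return peaks / fs


def r_peak_impulse_train(r_times: np.ndarray, fs: float, n: int, half_width_s: float = 0.01) -> np.ndarray:
    """Triangular-pulse train at R-peak samples (robust to +/-1 sample jitter)."""
    train = np.zeros(n)
    idx = np.round(np.asarray(r_times) * fs).astype(int)
    train[idx[(idx >= 0) & (idx < n)]] = 1.0
    hw = max(1, int(round(half_width_s * fs)))
    tri = 1.0 - np.abs(np.arange(-hw, hw + 1)) / (hw + 1)
    return np.convolve(train, tri, mode="same")


def estimate_lag(
    r_times_wearable: np.ndarray,
    r_times_reference: np.ndarray,
    fs: float,
    n: int,
    max_lag_s: float = 0.5,
    ambiguity_ratio: float = 0.99,
) -> int:
    """Lag (samples) by which the reference leads/lags the wearable stream.

    Positive lag means the reference stream is delayed.  The lag is the
    argmax of the cross-correlation of the two R-peak trains, searched within
    ``max_lag_s`` (kept below one R-R interval so the periodic aliases of the
    beat train are excluded).  If a second, non-adjacent lag reaches
    ``ambiguity_ratio`` of the maximum the alignment is flagged ambiguous.
    """
    a = r_peak_impulse_train(r_times_wearable, fs, n)
    b = r_peak_impulse_train(r_times_reference, fs, n)
    max_lag = int(round(max_lag_s * fs))
    corr = signal.correlate(b, a, mode="full")
    lags = signal.correlation_lags(len(b), len(a), mode="full")
    window = (lags >= -max_lag) & (lags <= max_lag)
    corr, lags = corr[window], lags[window]
    best = int(np.argmax(corr))
    # ambiguity: another local neighbourhood (beyond +/-30 ms) nearly as good
    guard = int(round(0.03 * fs))
    masked = corr.copy()
    lo, hi = max(0, best - guard), min(len(corr), best + guard + 1)
    masked[lo:hi] = -np.inf
    if np.max(masked) >= ambiguity_ratio * corr[best] and corr[best] > 0:
        raise AlignmentError(
            f"ambiguous alignment: competing lag {lags[int(np.argmax(masked))]} "
            f"within {100 * (1 - ambiguity_ratio):.0f}% of best lag {lags[best]}"
        )
    return int(lags[best])


def align_to_reference(session, min_peaks: int = 5, max_lag_s: float = 0.5):
    """Align the reference stream (ecg_ref, abp) to the wearable stream.

    Detects R-peaks on both ECGs, estimates the integer lag from the
    cross-correlation of their peak trains, shifts the lagging group and
    truncates all channels to the common support.  Returns a new ``Session``
    with ``alignment_lag_samples`` set.  Idempotent: a second application
    finds lag 0.
    """
    from pttbp.session import REFERENCE_CHANNELS, Channel, Session

    fs = session.fs
    r_w = detect_r_peaks(session.channel("ecg_wearable").samples, fs, raw=True)
    r_r = detect_r_peaks(session.channel("ecg_ref").samples, fs, raw=True)
    if len(r_w) < min_peaks or len(r_r) < min_peaks:
        raise ValueError(
            f"need >= {min_peaks} R peaks on both ECGs (got {len(r_w)}, {len(r_r)})"
        )
    n = max(len(ch.samples) for ch in session.channels.values())
    lag = estimate_lag(r_w, r_r, fs, n, max_lag_s=max_lag_s)

    channels: dict[str, Channel] = {}
    for name, ch in session.channels.items():
        samples = ch.samples
        if name in REFERENCE_CHANNELS and lag > 0:
            samples = samples[lag:]
        elif name not in REFERENCE_CHANNELS and lag < 0:
            samples = samples[-lag:]
        channels[name] = replace(ch, samples=samples)
    n_common = min(len(ch.samples) for ch in channels.values())
    for name, ch in channels.items():
        channels[name] = replace(ch, samples=ch.samples[:n_common])
    return Session(
        demographics=session.demographics,
        channels=channels,
        annotations=list(session.annotations),
        alignment_lag_samples=abs(lag),
    )


def filter_session(session, bands: dict | None = None, abp_window_ms: float = ABP_SMOOTH_MS):
    """Band-pass every channel with its role's default band; smooth the ABP."""
    from pttbp.session import Channel, Session

    bands = dict(DEFAULT_BANDS, **(bands or {}))
    fs = session.fs
    channels: dict[str, Channel] = {}
    for name, ch in session.channels.items():
        if name in ("ecg_wearable", "ecg_ref"):
            out = bandpass_fir(ch.samples, fs, FilterSpec(*bands["ecg"]))
        elif name == "scg_z":
            out = bandpass_fir(ch.samples, fs, FilterSpec(*bands["scg"]))
        elif name.startswith("ppg"):
            out = bandpass_fir(ch.samples, fs, FilterSpec(*bands["ppg"]))
        elif name == "abp":
            out = smooth_moving_average(ch.samples, fs, abp_window_ms)
        else:
            out = ch.samples
        channels[name] = replace(ch, samples=out)
    return Session(
        demographics=session.demographics,
        channels=channels,
        annotations=list(session.annotations),
        alignment_lag_samples=session.alignment_lag_samples,
    )
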