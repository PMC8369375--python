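"""Synthetic multimodal sessions with known ground truth.

The generator emits the seven synchronized 1 kHz channels of a wearable
PTT recording (wearable ECG, z-axis SCG, three PPG wavelengths, reference
ECG, continuous ABP) for a protocol schedule of tasks, together with a
:class:`GroundTruthRecord` carrying every per-beat fiducial time and the
law that links PTT to blood pressure.

Ground-truth law
----------------
Each participant has one set of calibration coefficients per BP component
(DBP, MAP, SBP) and a per-task inverse-PTT profile; the task BP values are
*derived* from the law, ``BP_c = K1_c / PTT + K2_c``, so all three
components are exactly consistent with the single PTT the device measures.
Within each task the generator then guarantees, by construction:

* ``ao_time = r_time + pep_s`` (SCG burst centred at the AO instant),
* ``foot_time = ao_time + ptt_true`` (the PPG waveform is phase-calibrated
  so that its intersecting-tangent foot lands exactly there),
* per-beat ABP min / max / mean equal the task's true DBP / SBP / MAP
  (the pulse carries flat plateaus wider than the 50 ms smoothing window).

Waveform morphology is deliberately simple and band-limited: the PPG beat
is built from harmonics 2..K of the heart rate that fall inside the flat
region of the 1-8 Hz analysis band, so linear-phase filtering leaves the
fiducial geometry untouched; the SCG AO marker is a Gabor burst centred in
the 1-40 Hz band; the ECG R-wave is a symmetric bump.  Noise (white,
per-channel), Poisson-timed motion-artifact bursts, heart-rate jitter, a
wearable/reference clock lag, and wavelength-dependent PPG amplitude
scaling (emulating melanin/BMI-dependent optical SNR: IR best, green
worst) are all configurable and default to zero-mean, reproducible draws
from a single seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from pttbp.fiducials import ppg_foot_intersecting_tangent
from pttbp.session import (
    Channel,
    Demographics,
    MEASUREMENT_TASKS,
    PPG_WAVELENGTHS_NM,
    REFERENCE_CHANNELS,
    Session,
    TaskAnnotation,
    CHANNEL_UNITS,
)

BP_COMPONENTS = ("DBP", "MAP", "SBP")

#: harmonics of the heart rate used for the PPG waveform must stay below
#: this frequency so the 1-8 Hz analysis band passes them unchanged
PPG_HARMONIC_MAX_HZ = 6.9

DEFAULT_TASK_INVPTT = {
    "sit_baseline": 5.0,
    "stand_baseline": 8.0,
    "rest": 3.5,
    "mental_arithmetic": 12.0,
    "cold_pressor": 14.5,
    "recovery_early": 10.0,
    "recovery_late": 5.5,
}


# ---------------------------------------------------------------------------
# ground-truth law


@dataclass
class GroundTruthLaw:
    """Per-participant calibration truth and per-task true PTT.

    ``k1`` (mm Hg*s) and ``k2`` (mm Hg) map PTT to BP per component via
    ``BP = K1/PTT + K2``; ``task_invptt`` holds 1/PTT (1/s) per task label.
    """

    k1: dict[str, float]
    k2: dict[str, float]
    task_invptt: dict[str, float]
    pep_s: float = 0.06

    def __post_init__(self) -> None:
        for c in BP_COMPONENTS:
            if c not in self.k1 or c not in self.k2:
                raise ValueError(f"law missing component {c}")
            if self.k1[c] <= 0:
                raise ValueError(f"K1[{c}] must be positive")
        for task, inv in self.task_invptt.items():
            ptt = 1.0 / inv
            if not (0.05 < ptt < 0.5):
                raise ValueError(f"task {task!r}: PTT {ptt:.3f} s outside (0.05, 0.5)")
        dbp_min = min(self.bp("DBP", t) for t in self.task_invptt)
        if self.k2["DBP"] >= dbp_min:
            raise ValueError(f"K2[DBP]={self.k2['DBP']} must be below min task DBP {dbp_min:.1f}")
        for t in self.task_invptt:
            sbp, dbp, map_ = self.task_bp(t)
            if not dbp <= map_ <= sbp:
                raise ValueError(f"task {t!r}: BP ordering violated ({dbp}, {map_}, {sbp})")

    def ptt(self, task: str) -> float:
        return 1.0 / self.task_invptt[task]

    def bp(self, component: str, task: str) -> float:
        return self.k1[component] * self.task_invptt[task] + self.k2[component]

    def task_bp(self, task: str) -> tuple[float, float, float]:
        """(SBP, DBP, MAP) in mm Hg for one task."""
        return self.bp("SBP", task), self.bp("DBP", task), self.bp("MAP", task)

    @property
    def tasks(self) -> list[str]:
        return list(self.task_invptt)


def default_law(
    k1_dbp: float = 2.0,
    k2_dbp: float = 60.0,
    task_invptt: dict[str, float] | None = None,
    pep_s: float = 0.06,
    k1_increments: tuple[float, float] = (0.8, 1.6),
    k2_increments: tuple[float, float] = (15.0, 32.0),
) -> GroundTruthLaw:
    """A physiologically plausible law built around the DBP coefficients.

    MAP and SBP coefficients sit above the DBP ones by fixed increments so
    the component ordering DBP <= MAP <= SBP holds at every task and the MAP
    sits at a realistic fraction (~0.45) of the pulse pressure.
    """
    inc1m, inc1s = k1_increments
    inc2m, inc2s = k2_increments
    return GroundTruthLaw(
        k1={"DBP": k1_dbp, "MAP": k1_dbp + inc1m, "SBP": k1_dbp + inc1s},
        k2={"DBP": k2_dbp, "MAP": k2_dbp + inc2m, "SBP": k2_dbp + inc2s},
        task_invptt=dict(task_invptt or DEFAULT_TASK_INVPTT),
        pep_s=pep_s,
    )


def random_law(
    rng: np.random.Generator,
    k1_dbp_range: tuple[float, float] = (1.0, 3.0),
    k2_dbp_range: tuple[float, float] = (50.0, 75.0),
    min_map_span_mm_hg: float = 25.5,
    n_tasks: int = 7,
    pep_s: float = 0.06,
) -> GroundTruthLaw:
    """Draw a participant law with DBP coefficients uniform on the given
    ranges and a per-task inverse-PTT profile wide enough that the MAP spans
    at least ``min_map_span_mm_hg`` across tasks (a well-conditioned
    calibration needs a large BP dynamic range) while every task PTT stays
    physiologic and inside the PAT gate."""
    k1 = float(rng.uniform(*k1_dbp_range))
    k2 = float(rng.uniform(*k2_dbp_range))
    k1_map = k1 + 0.8
    inv_lo_min, inv_hi_max = 2.6, 17.4  # PTT in (0.057, 0.385) s
    span = min(min_map_span_mm_hg / k1_map, inv_hi_max - inv_lo_min)
    lo = float(rng.uniform(inv_lo_min, inv_hi_max - span))
    labels = list(DEFAULT_TASK_INVPTT)[:n_tasks]
    invptt = dict(zip(labels, np.linspace(lo, lo + span, n_tasks)))
    return default_law(k1_dbp=k1, k2_dbp=k2, task_invptt=invptt, pep_s=pep_s)


# ---------------------------------------------------------------------------
# noise model


@dataclass
class NoiseModel:
    """Additive noise, motion artifacts, PPG optics, and heart-rate jitter.

    ``ppg_amplitude_scale`` emulates the wavelength dependence of optical
    penetration: IR keeps the full pulse amplitude while red and green are
    progressively attenuated (so with a common noise floor the SNR ordering
    is IR > red > green, as on skin with high melanin or BMI).
    """

    channel_noise_sd: dict[str, float] = field(
        default_factory=lambda: {
            "ecg_wearable": 0.03,
            "ecg_ref": 0.03,
            "scg_z": 0.05,
            "ppg": 0.05,
            "abp": 0.5,
        }
    )
    ppg_amplitude_scale: dict[str, float] = field(
        default_factory=lambda: {"ppg_ir": 1.0, "ppg_red": 0.6, "ppg_green": 0.3}
    )
    burst_rate_per_min: float = 0.5
    burst_amplitude_factor: float = 10.0
    burst_duration_range_s: tuple[float, float] = (0.5, 2.0)
    hr_mean_bpm: float = 70.0
    hr_sd_bpm: float = 3.0

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.channel_noise_sd.values()):
            raise ValueError("noise SDs must be >= 0")
        if any(not (0 < s <= 1) for s in self.ppg_amplitude_scale.values()):
            raise ValueError("PPG amplitude scales must lie in (0, 1]")
        if self.hr_mean_bpm <= 0 or self.hr_sd_bpm < 0:
            raise ValueError("heart-rate parameters out of range")

    @classmethod
    def zero(cls, hr_mean_bpm: float = 70.0) -> "NoiseModel":
        """Noise-free, jitter-free, artifact-free conditions."""
        return cls(
            channel_noise_sd={k: 0.0 for k in ("ecg_wearable", "ecg_ref", "scg_z", "ppg", "abp")},
            burst_rate_per_min=0.0,
            hr_mean_bpm=hr_mean_bpm,
            hr_sd_bpm=0.0,
        )

    def scaled(self, factor: float) -> "NoiseModel":
        """Same model with all additive noise SDs multiplied by ``factor``."""
        return replace(
            self, channel_noise_sd={k: v * factor for k, v in self.channel_noise_sd.items()}
        )


# ---------------------------------------------------------------------------
# ground-truth record


@dataclass
class GroundTruthRecord:
    """Per-beat fiducial truth plus the law/noise/seed that generated it.

    ``beats`` columns: r_time_s, ao_time_s, foot_time_s, ptt_s, pat_s, task.
    The foot time is wavelength-independent by construction (all three PPG
    wavelengths share the pulse timing and differ only in amplitude).
    """

    beats: pd.DataFrame
    task_bp: dict[str, tuple[float, float, float]]
    law: GroundTruthLaw
    noise: NoiseModel
    seed: int
    lag_samples: int = 0

    def task_ptt(self, task: str) -> float:
        return self.law.ptt(task)

    def to_json(self, path) -> None:
        payload = {
            "beats": self.beats.to_dict(orient="list"),
            "task_bp": {k: list(v) for k, v in self.task_bp.items()},
            "law": asdict(self.law),
            "noise": asdict(self.noise),
            "seed": self.seed,
            "lag_samples": self.lag_samples,
        }
        with open(path, "w") as f:
            json.dump(payload, f, indent=1)


# ---------------------------------------------------------------------------
# beat templates


@dataclass
class TemplateConfig:
    fs: float = 1000.0
    min_rr_s: float = 0.7
    ecg_r_amplitude: float = 1.0
    ecg_r_sigma_s: float = 0.008
    ecg_t_amplitude: float = 0.15
    ecg_t_offset_s: float = 0.25
    ecg_t_sigma_s: float = 0.05
    scg_ao_offset_s: float = 0.06
    scg_sigma_s: float = 0.018
    scg_freq_hz: float = 20.0
    ppg_rise_s: float = 0.12
    ppg_fall_s: float = 0.32
    ppg_foot_phase: float = 0.30
    abp_min: float = 80.0
    abp_max: float = 120.0
    abp_mean_fraction: float = 0.45
    abp_transition_fraction: float = 0.18


@dataclass
class BeatTemplates:
    """Seed morphologies sampled at ``fs`` over one nominal beat."""

    config: TemplateConfig
    ecg: np.ndarray
    scg: np.ndarray
    ppg: np.ndarray
    abp: np.ndarray

    @property
    def fs(self) -> float:
        return self.config.fs


def _gaussian_bump(t: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _gabor_burst(t: np.ndarray, center: float, sigma: float, freq: float) -> np.ndarray:
    return _gaussian_bump(t, center, sigma) * np.cos(2 * np.pi * freq * (t - center))


def _raised_cosine(u: np.ndarray) -> np.ndarray:
    """Smooth 0 -> 1 transition on u in [0, 1]."""
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(u, 0.0, 1.0)))


def _ppg_phase_shape(u: np.ndarray, rise_frac: float, fall_frac: float, foot_phase: float) -> np.ndarray:
    """Base PPG morphology on beat phase u in [0, 1): flat baseline, a
    raised-cosine systolic upstroke starting at ``foot_phase``, and a
    raised-cosine decay back to baseline."""
    u = np.mod(u, 1.0)
    x = np.zeros_like(u)
    up = (u >= foot_phase) & (u < foot_phase + rise_frac)
    x[up] = _raised_cosine((u[up] - foot_phase) / rise_frac)
    down = (u >= foot_phase + rise_frac) & (u < foot_phase + rise_frac + fall_frac)
    x[down] = 1.0 - _raised_cosine((u[down] - foot_phase - rise_frac) / fall_frac)
    return x


def _abp_phase_shape(u: np.ndarray, mean_fraction: float, transition_fraction: float,
                     rise_start: float = 0.10) -> np.ndarray:
    """Normalized ABP pulse on phase u in [0, 1): 0/1 plateaus joined by
    raised cosines, with the systolic-plateau width solved so the time
    average equals ``mean_fraction``.  Plateaus stay wide enough that a
    50 ms moving average leaves the extrema exact."""
    mu = mean_fraction
    rho = transition_fraction
    # each transition contributes rho/2 to the mean; plateau width b gives b
    rho = float(np.clip(rho, 0.02, min(mu - 0.10, 0.90 - mu)))
    if not (0.11 <= mu <= 0.89):
        raise ValueError(f"ABP mean fraction {mu:.3f} infeasible for plateau morphology")
    b = mu - rho  # systolic plateau fraction
    a_total = 1.0 - b - 2 * rho  # diastolic plateau fraction (wraps the boundary)
    a1 = min(rise_start, a_total)
    u = np.mod(u, 1.0)
    x = np.zeros_like(u)
    seg = [(a1, a1 + rho), (a1 + rho, a1 + rho + b), (a1 + rho + b, a1 + 2 * rho + b)]
    rise = (u >= seg[0][0]) & (u < seg[0][1])
    x[rise] = _raised_cosine((u[rise] - seg[0][0]) / rho)
    x[(u >= seg[1][0]) & (u < seg[1][1])] = 1.0
    fall = (u >= seg[2][0]) & (u < seg[2][1])
    x[fall] = 1.0 - _raised_cosine((u[fall] - seg[2][0]) / rho)
    return x


def make_beat_templates(config: TemplateConfig | None = None) -> BeatTemplates:
    """Seed waveforms for one beat: ECG R-wave, SCG AO burst, PPG pulse, ABP pulse.

    Raises ``ValueError`` when a template would not fit the shortest allowed
    R-R interval.
    """
    cfg = config or TemplateConfig()
    fs, rr = cfg.fs, cfg.min_rr_s
    if cfg.ecg_t_offset_s + 4 * cfg.ecg_t_sigma_s > rr or cfg.scg_ao_offset_s + 6 * cfg.scg_sigma_s > rr:
        raise ValueError("template extends beyond the shortest R-R interval")
    rise_frac, fall_frac = cfg.ppg_rise_s / rr, cfg.ppg_fall_s / rr
    if cfg.ppg_foot_phase + rise_frac + fall_frac >= 0.999:
        raise ValueError("PPG template longer than the shortest R-R interval")
    t = np.arange(int(round(rr * fs))) / fs
    ecg = cfg.ecg_r_amplitude * _gaussian_bump(t, 3 * cfg.ecg_r_sigma_s + 0.0, cfg.ecg_r_sigma_s)
    ecg += cfg.ecg_t_amplitude * _gaussian_bump(t, cfg.ecg_t_offset_s, cfg.ecg_t_sigma_s)
    scg = _gabor_burst(t, cfg.scg_ao_offset_s, cfg.scg_sigma_s, cfg.scg_freq_hz)
    ppg = _ppg_phase_shape(t / rr, rise_frac, fall_frac, cfg.ppg_foot_phase)
    beta = _abp_phase_shape(t / rr, cfg.abp_mean_fraction, cfg.abp_transition_fraction)
    abp = cfg.abp_min + (cfg.abp_max - cfg.abp_min) * beta
    return BeatTemplates(config=cfg, ecg=ecg, scg=scg, ppg=ppg, abp=abp)


# ---------------------------------------------------------------------------
# band-limited PPG synthesis


def _ppg_harmonic_coeffs(f0: float, cfg: TemplateConfig, n_dense: int = 4096) -> dict[int, complex]:
    """Fourier coefficients of the base PPG morphology on harmonics k >= 2
    of the heart rate that stay below the flat region of the 1-8 Hz band.

    The fundamental (k = 1) is excluded on purpose: it sits in the
    transition band of the 1 Hz high-pass, so a waveform built without it
    passes the analysis filter essentially unchanged and the constructed
    fiducial geometry survives preprocessing exactly.
    """
    u = np.arange(n_dense) / n_dense
    t0 = 1.0 / f0
    shape = _ppg_phase_shape(u, cfg.ppg_rise_s / t0, cfg.ppg_fall_s / t0, cfg.ppg_foot_phase)
    spec = np.fft.rfft(shape) / n_dense
    k_max = int(math.floor(PPG_HARMONIC_MAX_HZ / f0))
    return {k: spec[k] for k in range(2, max(k_max, 2) + 1)}


def _synth_harmonics(coeffs: dict[int, complex], f0: float, t: np.ndarray) -> np.ndarray:
    x = np.zeros_like(t, dtype=float)
    for k, c in coeffs.items():
        x += 2.0 * (c.real * np.cos(2 * np.pi * k * f0 * t) - c.imag * np.sin(2 * np.pi * k * f0 * t))
    return x


def _shift_coeffs(coeffs: dict[int, complex], f0: float, delta_s: float) -> dict[int, complex]:
    """Exact time shift x(t) -> x(t - delta) in the harmonic domain."""
    return {k: c * np.exp(-1j * 2 * np.pi * k * f0 * delta_s) for k, c in coeffs.items()}


def calibrated_ppg_coeffs(
    f0: float, fs: float, foot_target_s: float, cfg: TemplateConfig, n_iter: int = 3
) -> dict[int, complex]:
    """Harmonic coefficients whose intersecting-tangent foot, measured the
    same way the pipeline measures it, lies at ``foot_target_s`` from the
    beat start."""
    coeffs = _ppg_harmonic_coeffs(f0, cfg)
    t0 = 1.0 / f0
    t = np.arange(int(round(t0 * fs))) / fs
    for _ in range(n_iter):
        beat = _synth_harmonics(coeffs, f0, t)
        foot = ppg_foot_intersecting_tangent(beat, fs)
        err = foot_target_s - foot
        if abs(err) < 1e-6:
            break
        coeffs = _shift_coeffs(coeffs, f0, err)
    return coeffs


def _warp_phase(tau: np.ndarray, rr: float, t0: float, tau_fix: float) -> np.ndarray:
    """Map time-in-beat [0, rr) onto the nominal beat [0, t0): the early
    portion (which carries the fiducials) is kept 1:1 and R-R jitter is
    absorbed by linearly stretching the tail."""
    if rr <= tau_fix or t0 <= tau_fix:
        return tau * (t0 / rr)
    out = np.where(tau <= tau_fix, tau, tau_fix + (tau - tau_fix) * (t0 - tau_fix) / (rr - tau_fix))
    return out


# ---------------------------------------------------------------------------
# schedules


def default_schedule() -> list[TaskAnnotation]:
    """Protocol-shaped schedule: sitting and standing baselines, then the
    post-perturbation measurement segments (mental arithmetic, cold pressor,
    early and late exercise recovery) with a rest in between.  Labels mark
    the perturbation whose after-effect each segment measures; the device
    records no PTT during the exercise itself, so no ``exercise`` segment is
    scheduled by default."""
    spec = [
        ("sit_baseline", 120.0),
        ("stand_baseline", 120.0),
        ("rest", 60.0),
        ("mental_arithmetic", 60.0),
        ("cold_pressor", 60.0),
        ("recovery_early", 60.0),
        ("recovery_late", 60.0),
    ]
    out, t = [], 0.0
    for label, dur in spec:
        out.append(TaskAnnotation(label, t, t + dur))
        t += dur
    return out


def compact_schedule(task_s: float = 30.0, tasks: tuple[str, ...] | None = None) -> list[TaskAnnotation]:
    """Shorter schedule with the same task set (for small studies/tests)."""
    labels = tasks or tuple(DEFAULT_TASK_INVPTT)
    out, t = [], 0.0
    for label in labels:
        out.append(TaskAnnotation(label, t, t + task_s))
        t += task_s
    return out


# ---------------------------------------------------------------------------
# session synthesis


def _default_demographics(participant_id: str = "sim-000") -> Demographics:
    return Demographics(
        participant_id=participant_id,
        age=30.0,
        sex="male",
        race="other",
        height_cm=172.0,
        weight_kg=70.0,
    )


def simulate_session(
    law: GroundTruthLaw,
    noise: NoiseModel,
    schedule: list[TaskAnnotation] | None = None,
    seed: int = 0,
    lag_samples: int = 150,
    fs: float = 1000.0,
    pad_s: float = 2.0,
    demographics: Demographics | None = None,
    template_config: TemplateConfig | None = None,
) -> tuple[Session, GroundTruthRecord]:
    """Generate one synthetic session and its ground truth.

    The reference channels (ecg_ref, abp) are delayed by ``lag_samples`` to
    exercise the alignment stage; all truth times are on the wearable clock.
    Identical seeds give identical output.
    """
    schedule = schedule if schedule is not None else default_schedule()
    cfg = template_config or TemplateConfig()
    rng = np.random.default_rng(seed)

    anns = sorted(schedule, key=lambda a: a.start_s)
    for prev, nxt in zip(anns, anns[1:]):
        if nxt.start_s < prev.end_s - 1e-9:
            raise ValueError(f"schedule tasks {prev.label!r} and {nxt.label!r} overlap")
    t0_nominal = 60.0 / noise.hr_mean_bpm
    for a in anns:
        if a.label in MEASUREMENT_TASKS:
            if a.label not in law.task_invptt:
                raise ValueError(f"law has no PTT/BP for task {a.label!r}")
            if a.duration_s < 12 * t0_nominal:
                raise ValueError(
                    f"task {a.label!r} ({a.duration_s:.0f} s) holds fewer than 12 beats"
                )

    # shift annotations so filter edge transients fall in the lead-in pad
    anns = [TaskAnnotation(a.label, a.start_s + pad_s, a.end_s + pad_s) for a in anns]
    duration = anns[-1].end_s + pad_s
    n = int(round(duration * fs))
    t_grid = np.arange(n) / fs

    # --- R-time sequence with normally distributed R-R jitter
    rr_sd = 60.0 * noise.hr_sd_bpm / noise.hr_mean_bpm**2
    r_times = [0.05]
    while r_times[-1] < duration:
        rr = t0_nominal + (rng.normal(0.0, rr_sd) if rr_sd > 0 else 0.0)
        rr = float(np.clip(rr, 0.35, 1.6))
        r_times.append(r_times[-1] + rr)
    r_times = np.array(r_times)

    def task_of(time_s: float) -> str | None:
        for a in anns:
            if a.start_s <= time_s < a.end_s and a.label in MEASUREMENT_TASKS:
                return a.label
        return None

    f0 = 1.0 / t0_nominal
    ppg_coeffs = {
        task: calibrated_ppg_coeffs(f0, fs, law.pep_s + law.ptt(task), cfg)
        for task in law.task_invptt
    }
    abp_shapes = {}
    for task in law.task_invptt:
        sbp, dbp, map_ = law.task_bp(task)
        mu = (map_ - dbp) / (sbp - dbp) if sbp > dbp else 0.5
        abp_shapes[task] = (dbp, sbp - dbp, mu)

    ecg = np.zeros(n)
    scg = np.zeros(n)
    ppg = np.zeros(n)
    abp = np.zeros(n)

    templates = make_beat_templates(cfg)  # validates template feasibility
    del templates

    truth_rows = []
    current_task = anns[0].label
    dense_u = None
    for i in range(len(r_times) - 1):
        r, r_next = r_times[i], r_times[i + 1]
        rr = r_next - r
        task = task_of(r) or current_task
        current_task = task
        i0, i1 = int(np.ceil(r * fs)), min(int(np.ceil(r_next * fs)), n)
        if i0 >= n:
            break
        tau = t_grid[i0:i1] - r

        # ECG: R bump at the R time plus a small T wave
        lo = max(0, int((r - 0.06) * fs))
        hi = min(n, int((r + 0.06) * fs))
        ecg[lo:hi] += cfg.ecg_r_amplitude * _gaussian_bump(t_grid[lo:hi], r, cfg.ecg_r_sigma_s)
        t_t = r + cfg.ecg_t_offset_s
        lo, hi = max(0, int((t_t - 0.25) * fs)), min(n, int((t_t + 0.25) * fs))
        ecg[lo:hi] += cfg.ecg_t_amplitude * _gaussian_bump(t_grid[lo:hi], t_t, cfg.ecg_t_sigma_s)

        # SCG: Gabor burst centred at the AO instant
        ao = r + law.pep_s
        lo, hi = max(0, int((ao - 0.12) * fs)), min(n, int((ao + 0.12) * fs))
        scg[lo:hi] += _gabor_burst(t_grid[lo:hi], ao, cfg.scg_sigma_s, cfg.scg_freq_hz)

        # PPG and ABP: nominal-beat waveforms, R-R jitter absorbed in the tail
        foot_off = law.pep_s + law.ptt(task)
        tau_fix = min(max(0.55 * t0_nominal, foot_off + 0.10), 0.85 * t0_nominal)
        tau_n = _warp_phase(tau, rr, t0_nominal, tau_fix)
        ppg[i0:i1] = _synth_harmonics(ppg_coeffs[task], f0, tau_n)
        dbp, pp, mu = abp_shapes[task]
        abp[i0:i1] = dbp + pp * _abp_phase_shape(tau_n / t0_nominal, mu, cfg.abp_transition_fraction)

        ann = next((a for a in anns if a.label == task and a.start_s <= r < a.end_s), None)
        if ann is not None and r >= ann.start_s and r_next <= ann.end_s:
            ptt = law.ptt(task)
            foot = ao + ptt
            truth_rows.append(
                {
                    "r_time_s": r,
                    "ao_time_s": ao,
                    "foot_time_s": foot,
                    "ptt_s": ptt,
                    "pat_s": foot - r,
                    "task": task,
                }
            )

    # lead-in/out: hold the first/last beat's waveforms flat at baseline
    first_r = int(np.ceil(r_times[0] * fs))
    dbp0 = abp_shapes[anns[0].label][0]
    abp[:first_r] = dbp0

    # --- assemble channels: wavelength scaling, noise, artifacts, clock lag
    def noisy(x: np.ndarray, sd: float) -> np.ndarray:
        return x + rng.normal(0.0, sd, size=len(x)) if sd > 0 else x.copy()

    def with_bursts(x: np.ndarray, sd: float) -> np.ndarray:
        if noise.burst_rate_per_min <= 0 or sd <= 0:
            return x
        n_bursts = rng.poisson(noise.burst_rate_per_min * duration / 60.0)
        for _ in range(n_bursts):
            dur = rng.uniform(*noise.burst_duration_range_s)
            start = rng.uniform(0.0, max(duration - dur, 0.0))
            j0, j1 = int(start * fs), min(int((start + dur) * fs), len(x))
            burst = rng.normal(0.0, 1.0, j1 - j0)
            burst = np.convolve(burst, np.ones(20) / 20.0, mode="same")
            burst *= noise.burst_amplitude_factor * sd / max(np.std(burst), 1e-12)
            taper = np.hanning(j1 - j0)
            x[j0:j1] += burst * taper
        return x

    sd = noise.channel_noise_sd
    channels: dict[str, Channel] = {}
    channels["ecg_wearable"] = Channel("ecg_wearable", noisy(ecg, sd.get("ecg_wearable", 0.0)))
    channels["scg_z"] = Channel(
        "scg_z", with_bursts(noisy(scg, sd.get("scg_z", 0.0)), sd.get("scg_z", 0.0)), units="g"
    )
    for name, wl in PPG_WAVELENGTHS_NM.items():
        scale = noise.ppg_amplitude_scale.get(name, 1.0)
        channels[name] = Channel(
            name,
            with_bursts(noisy(scale * ppg, sd.get("ppg", 0.0)), sd.get("ppg", 0.0)),
            wavelength_nm=wl,
        )
    ecg_ref = noisy(ecg, sd.get("ecg_ref", 0.0))
    abp_ref = noisy(abp, sd.get("abp", 0.0))
    if lag_samples > 0:
        ecg_ref = np.concatenate([np.full(lag_samples, ecg_ref[0]), ecg_ref[:-lag_samples]])
        abp_ref = np.concatenate([np.full(lag_samples, abp_ref[0]), abp_ref[:-lag_samples]])
    channels["ecg_ref"] = Channel("ecg_ref", ecg_ref)
    channels["abp"] = Channel("abp", abp_ref, units="mm Hg")

    session = Session(
        demographics=demographics or _default_demographics(f"sim-{seed:03d}"),
        channels=channels,
        annotations=anns,
    )
    record = GroundTruthRecord(
        beats=pd.DataFrame(truth_rows),
        task_bp={task: law.task_bp(task) for task in law.task_invptt},
        law=law,
        noise=noise,
        seed=seed,
        lag_samples=lag_samples,
    )
    return session, record


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortGroupSpec:
    """Sampling distributions for one demographic group.

    K1/K2 refer to the DBP component (the coefficients compared across
    demographics); MAP and SBP coefficients follow by the fixed increments
    of :func:`default_law`.
    """

    name: str
    k1_dbp_mean: float = 2.0
    k1_dbp_sd: float = 0.5
    k2_dbp_mean: float = 62.0
    k2_dbp_sd: float = 5.0
    bmi_mean: float = 25.0
    bmi_sd: float = 3.0
    age_mean: float = 30.0
    age_sd: float = 8.0
    female_fraction: float = 0.4
    black_fraction: float = 0.2
    noise: NoiseModel = field(default_factory=NoiseModel)


def _sample_law(rng: np.random.Generator, spec: CohortGroupSpec) -> GroundTruthLaw:
    k1 = float(np.clip(rng.normal(spec.k1_dbp_mean, spec.k1_dbp_sd), 0.4, 6.0))
    k2 = float(np.clip(rng.normal(spec.k2_dbp_mean, spec.k2_dbp_sd), 45.0, 80.0))
    return default_law(k1_dbp=k1, k2_dbp=k2)


def _sample_demographics(
    rng: np.random.Generator, spec: CohortGroupSpec, participant_id: str
) -> Demographics:
    height = float(rng.normal(170.0, 9.0))
    bmi = float(np.clip(rng.normal(spec.bmi_mean, spec.bmi_sd), 16.0, 55.0))
    weight = bmi * (height / 100.0) ** 2
    return Demographics(
        participant_id=participant_id,
        age=float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 18.0, 90.0)),
        sex="female" if rng.uniform() < spec.female_fraction else "male",
        race="Black" if rng.uniform() < spec.black_fraction else "other",
        height_cm=height,
        weight_kg=weight,
    )


def simulate_cohort(
    group_specs: list[CohortGroupSpec],
    n_per_group: int,
    seed: int = 0,
    signals: bool = True,
    schedule: list[TaskAnnotation] | None = None,
) -> tuple[list[Session | None], pd.DataFrame, list[GroundTruthRecord | None]]:
    """Sample ``n_per_group`` participants per group.

    Returns (sessions, truth table, truth records).  The truth table holds
    one row per participant with demographics and the true coefficients per
    component.  With ``signals=False`` no waveforms are synthesized (the
    sessions/records lists hold ``None``); this coefficient-level mode is
    what the operating-characteristic studies of the group comparisons use.
    """
    if not group_specs:
        raise ValueError("no group specs given")
    if n_per_group <= 0:
        raise ValueError("n_per_group must be positive")
    rng = np.random.default_rng(seed)
    sessions: list[Session | None] = []
    records: list[GroundTruthRecord | None] = []
    rows = []
    for gi, spec in enumerate(group_specs):
        for pi in range(n_per_group):
            pid = f"{spec.name}-{pi:03d}"
            law = _sample_law(rng, spec)
            demo = _sample_demographics(rng, spec, pid)
            row = {
                "participant_id": pid,
                "group": spec.name,
                "age": demo.age,
                "sex": demo.sex,
                "race": demo.race,
                "bmi": demo.bmi,
                "obesity_class": demo.obesity_class,
            }
            for c in BP_COMPONENTS:
                row[f"K1_{c}"] = law.k1[c]
                row[f"K2_{c}"] = law.k2[c]
            rows.append(row)
            if signals:
                sess_seed = int(rng.integers(0, 2**31 - 1))
                session, record = simulate_session(
                    law, spec.noise, schedule=schedule, seed=sess_seed, demographics=demo
                )
                sessions.append(session)
                records.append(record)
            else:
                sessions.append(None)
                records.append(None)
    return sessions, pd.DataFrame(rows), records
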