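"""Session data model and HDF5 round trip.

A *session* is one participant's synchronized multichannel recording:
wearable ECG, z-axis seismocardiogram (SCG), three wrist PPG wavelengths,
plus a reference ECG and a continuous arterial blood pressure (ABP)
waveform, all sampled at 1 kHz, together with task annotations and
demographics.

Container layout (HDF5, one file per session)::

    /channels/<name>      float64 dataset, attrs: fs, units, wavelength_nm
    attrs: format_version, demographics (JSON), annotations (JSON),
           alignment_lag_samples (-1 when unset)

Unknown channels are preserved on round trip (forward compatibility).
Time convention: sample index 0 is t = 0 s; intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

FORMAT_VERSION = "pttbp-session-1"

#: channel roles every session must carry
REQUIRED_CHANNELS = (
    "ecg_wearable",
    "scg_z",
    "ppg_green",
    "ppg_red",
    "ppg_ir",
    "ecg_ref",
    "abp",
)

#: channels acquired by the wearable (share its clock)
WEARABLE_CHANNELS = ("ecg_wearable", "scg_z", "ppg_green", "ppg_red", "ppg_ir")
#: channels acquired by the reference system (may lead/lag the wearable)
REFERENCE_CHANNELS = ("ecg_ref", "abp")

PPG_WAVELENGTHS_NM = {"ppg_green": 526.0, "ppg_red": 660.0, "ppg_ir": 950.0}

CHANNEL_UNITS = {
    "ecg_wearable": "a.u.",
    "scg_z": "g",
    "ppg_green": "a.u.",
    "ppg_red": "a.u.",
    "ppg_ir": "a.u.",
    "ecg_ref": "a.u.",
    "abp": "mm Hg",
}

TASK_LABELS = (
    "sit_baseline",
    "stand_baseline",
    "rest",
    "mental_arithmetic",
    "cold_pressor",
    "exercise",
    "recovery_early",
    "recovery_late",
)

#: tasks during which the device can record PTT (no measurement mid-exercise)
MEASUREMENT_TASKS = tuple(t for t in TASK_LABELS if t != "exercise")

OBESITY_CLASSES = ("nonobese", "I", "II", "III")


class SessionFormatError(Exception):
    """Raised when a session file is missing, corrupt, or of unknown version."""


@dataclass
class Channel:
    """One recorded signal with its physical units and sampling rate."""

    name: str
    samples: np.ndarray
    fs: float = 1000.0
    wavelength_nm: Optional[float] = None
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


@dataclass
class TaskAnnotation:
    """A labelled protocol segment, seconds from record start, [start, end)."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(
                f"annotation {self.label!r}: end_s ({self.end_s}) must exceed start_s ({self.start_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def obesity_class_from_bmi(bmi: float) -> str:
    """NHLBI obesity classes: I = 30-34.9, II = 35-39.9, III = >= 40 kg/m^2."""
    if bmi >= 40:
        return "III"
    if bmi >= 35:
        return "II"
    if bmi >= 30:
        return "I"
    return "nonobese"


@dataclass
class Demographics:
    participant_id: str
    age: float
    sex: str
    race: str
    height_cm: float
    weight_kg: float
    bmi: Optional[float] = None
    hypertensive_status: str = "normotensive"
    medications: list = field(default_factory=list)

    def __post_init__(self) -> None:
        derived = self.weight_kg / (self.height_cm / 100.0) ** 2
        if self.bmi is None:
            self.bmi = derived
        elif abs(self.bmi - derived) > 0.1:
            raise ValueError(
                f"participant {self.participant_id}: bmi {self.bmi:.2f} inconsistent "
                f"with weight/height^2 ({derived:.2f})"
            )

    @property
    def obesity_class(self) -> str:
        return obesity_class_from_bmi(self.bmi)

    @property
    def obese(self) -> bool:
        return self.bmi >= 30.0


@dataclass
class Session:
    """One participant's synchronized recording plus metadata."""

    demographics: Demographics
    channels: dict[str, Channel]
    annotations: list[TaskAnnotation]
    alignment_lag_samples: Optional[int] = None

    def channel(self, name: str) -> Channel:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(f"session has no channel {name!r}; present: {sorted(self.channels)}")

    @property
    def fs(self) -> float:
        return next(iter(self.channels.values())).fs

    @property
    def duration_s(self) -> float:
        return min(ch.duration_s for ch in self.channels.values())

    def tasks(self, measurement_only: bool = True) -> list[TaskAnnotation]:
        if measurement_only:
            return [a for a in self.annotations if a.label in MEASUREMENT_TASKS]
        return list(self.annotations)


# ---------------------------------------------------------------------------
# validation


def validate_session(session: Session) -> list[str]:
    """Report-only schema check; an empty list means the session is valid."""
    problems: list[str] = []
    for role in REQUIRED_CHANNELS:
        if role not in session.channels:
            problems.append(f"missing required channel {role!r}")
    for name, ch in session.channels.items():
        if ch.fs != 1000.0:
            problems.append(f"channel {name!r}: fs != 1000 (got {ch.fs})")
        if not np.all(np.isfinite(ch.samples)):
            problems.append(f"channel {name!r}: non-finite samples")
        expected_wl = PPG_WAVELENGTHS_NM.get(name)
        if expected_wl is not None and ch.wavelength_nm is None:
            problems.append(f"channel {name!r}: PPG channel missing wavelength_nm")
        if name in CHANNEL_UNITS and name not in PPG_WAVELENGTHS_NM and ch.wavelength_nm is not None:
            problems.append(f"channel {name!r}: non-PPG channel carries a wavelength")
    lengths = {name: len(ch.samples) for name, ch in session.channels.items()}
    if session.alignment_lag_samples is not None and len(set(lengths.values())) > 1:
        problems.append(f"aligned session has unequal channel lengths: {lengths}")
    duration = session.duration_s
    anns = sorted(session.annotations, key=lambda a: a.start_s)
    for a in anns:
        if a.label not in TASK_LABELS:
            problems.append(f"annotation label {a.label!r} unknown")
        if a.start_s < 0 or a.end_s > duration + 1e-9:
            problems.append(f"annotation {a.label!r} [{a.start_s}, {a.end_s}) outside record")
    for prev, nxt in zip(anns, anns[1:]):
        if nxt.start_s < prev.end_s - 1e-9:
            problems.append(f"annotations {prev.label!r} and {nxt.label!r} overlap")
    return problems


# ---------------------------------------------------------------------------
# HDF5 round trip


def _demographics_to_json(d: Demographics) -> str:
    payload = asdict(d)
    payload["obesity_class"] = d.obesity_class
    return json.dumps(payload, sort_keys=True)


def _demographics_from_json(s: str) -> Demographics:
    payload = json.loads(s)
    payload.pop("obesity_class", None)
    return Demographics(**payload)


def write_session(session: Session, path) -> None:
    """Write a validated session to one HDF5 file.

    Raises ``ValueError`` on an invalid session (the validation report is
    included in the message).  Two writes of the same session produce
    byte-identical files (dataset timestamps are disabled).
    """
    problems = validate_session(session)
    if problems:
        raise ValueError("invalid session: " + "; ".join(problems))
    path = Path(path)
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["demographics"] = _demographics_to_json(session.demographics)
        f.attrs["annotations"] = json.dumps(
            [asdict(a) for a in session.annotations], sort_keys=True
        )
        f.attrs["alignment_lag_samples"] = (
            -1 if session.alignment_lag_samples is None else int(session.alignment_lag_samples)
        )
        grp = f.create_group("channels", track_order=True)
        for name in sorted(session.channels):
            ch = session.channels[name]
            ds = grp.create_dataset(name, data=ch.samples.astype(np.float64), track_times=False)
            ds.attrs["fs"] = float(ch.fs)
            ds.attrs["units"] = ch.units
            ds.attrs["n_samples"] = len(ch.samples)
            if ch.wavelength_nm is not None:
                ds.attrs["wavelength_nm"] = float(ch.wavelength_nm)


def read_session(path) -> Session:
    """Read a session written by :func:`write_session`.

    Unknown extra channels are preserved.  Raises :class:`SessionFormatError`
    for a missing file, a version mismatch, or a channel whose stored length
    disagrees with its dataset (truncation).
    """
    path = Path(path)
    if not path.exists():
        raise SessionFormatError(f"no such session file: {path}")
    try:
        f = h5py.File(path, "r")
    except OSError as e:
        raise SessionFormatError(f"unreadable session file {path}: {e}") from e
    with f:
        version = f.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise SessionFormatError(
                f"{path}: format version {version!r} != expected {FORMAT_VERSION!r}"
            )
        demographics = _demographics_from_json(f.attrs["demographics"])
        annotations = [TaskAnnotation(**a) for a in json.loads(f.attrs["annotations"])]
        lag = int(f.attrs.get("alignment_lag_samples", -1))
        channels: dict[str, Channel] = {}
        for name, ds in f["channels"].items():
            samples = np.asarray(ds[...], dtype=float)
            declared = int(ds.attrs.get("n_samples", len(samples)))
            if declared != len(samples):
                raise SessionFormatError(
                    f"{path}: channel {name!r} corrupt length "
                    f"(declared {declared}, found {len(samples)})"
                )
            channels[name] = Channel(
                name=name,
                samples=samples,
                fs=float(ds.attrs.get("fs", 1000.0)),
                wavelength_nm=(
                    float(ds.attrs["wavelength_nm"]) if "wavelength_nm" in ds.attrs else None
                ),
                units=str(ds.attrs.get("units", "a.u.")),
            )
    return Session(
        demographics=demographics,
        channels=channels,
        annotations=annotations,
        alignment_lag_samples=None if lag < 0 else lag,
    )


def export_channels_csv(session: Session, path) -> None:
    """Write all channels as a single CSV (columns: t_s, one per channel)."""
    n = min(len(ch.samples) for ch in session.channels.values())
    data = {"t_s": np.arange(n) / session.fs}
    for name in sorted(session.channels):
        data[name] = session.channels[name].samples[:n]
    pd.DataFrame(data).to_csv(path, index=False)


def is_nan(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)
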