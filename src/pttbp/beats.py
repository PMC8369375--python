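"""Heartbeat segmentation and ensemble averaging.

Channels are split into beats on detected R-R boundaries (half-open sample
ranges, so the beats partition the signal), then ensemble-averaged in
10-beat windows with 50 % overlap to raise SNR.  Reference blood-pressure
values are read off the averaged ABP beat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class BeatSet:
    """R-gated beats of one channel: beat i spans [R_i, R_{i+1})."""

    channel: str
    beats: list[np.ndarray]
    start_times_s: list[float]
    r_times_s: np.ndarray
    fs: float

    def __len__(self) -> int:
        return len(self.beats)


@dataclass
class EnsembleBeat:
    """Average of 10 consecutive beats, truncated to the shortest member."""

    channel: str
    window_index: int
    member_indices: list[int]
    samples: np.ndarray
    start_time_s: float
    fs: float
    snr_db: float | None = None
    members: list[np.ndarray] = field(default_factory=list, repr=False)


def segment_heartbeats(signal: np.ndarray, r_times: np.ndarray, fs: float, channel: str = "") -> BeatSet:
    """One beat per R-R interval; beats concatenate back to [R_first, R_last)."""
    signal = np.asarray(signal, dtype=float)
    r_times = np.asarray(r_times, dtype=float)
    if len(r_times) < 2:
        raise ValueError(f"need >= 2 R times to segment, got {len(r_times)}")
    idx = np.round(r_times * fs).astype(int)
    idx = np.clip(idx, 0, len(signal))
    beats = [signal[a:b] for a, b in zip(idx[:-1], idx[1:])]
    starts = [a / fs for a in idx[:-1]]
    return BeatSet(channel=channel, beats=beats, start_times_s=starts, r_times_s=r_times, fs=fs)


def ensemble_windows(beatset: BeatSet, width: int = 10, hop: int = 5) -> list[EnsembleBeat]:
    """Sliding ensemble averages: window k covers beats [k*hop, k*hop + width).

    Count = floor((N - width)/hop) + 1; trailing beats that do not fill a
    final window are dropped.  Members are aligned at their R-anchored start
    and averaged over the common (shortest-member) length.
    """
    n = len(beatset)
    if n < width:
        raise ValueError(f"need >= {width} beats for one window, got {n}")
    ensembles = []
    for k in range((n - width) // hop + 1):
        members = list(range(k * hop, k * hop + width))
        beats = [beatset.beats[i] for i in members]
        m = min(len(b) for b in beats)
        stacked = np.stack([b[:m] for b in beats])
        ensembles.append(
            EnsembleBeat(
                channel=beatset.channel,
                window_index=k,
                member_indices=members,
                samples=stacked.mean(axis=0),
                start_time_s=beatset.start_times_s[members[0]],
                fs=beatset.fs,
                members=[b[:m] for b in beats],
            )
        )
    return ensembles


def abp_beat_bp(ensemble: EnsembleBeat) -> tuple[float, float, float]:
    """(SBP, DBP, MAP) of an averaged ABP beat: max, min, time-average."""
    if ensemble.channel != "abp":
        raise ValueError(f"expected an abp ensemble, got channel {ensemble.channel!r}")
    samples = ensemble.samples
    sbp = float(np.max(samples))
    dbp = float(np.min(samples))
    map_ = float(np.mean(samples))
    return sbp, dbp, map_


def beats_in_task(beatset: BeatSet, start_s: float, end_s: float) -> BeatSet:
    """Restrict to beats fully inside [start_s, end_s)."""
    keep = [
        i
        for i, (t0, beat) in enumerate(zip(beatset.start_times_s, beatset.beats))
        if t0 >= start_s and t0 + len(beat) / beatset.fs <= end_s
    ]
    return BeatSet(
        channel=beatset.channel,
        beats=[beatset.beats[i] for i in keep],
        start_times_s=[beatset.start_times_s[i] for i in keep],
        r_times_s=np.asarray([beatset.r_times_s[i] for i in keep]),
        fs=beatset.fs,
    )
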