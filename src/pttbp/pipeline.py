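"""End-to-end orchestration: session -> fiducials -> calibration -> reports.

Stage order follows the device's processing chain: align the wearable and
reference streams on their ECGs, band-pass filter, segment heartbeats on
R-R intervals per task, ensemble-average (10 beats, 50 % overlap), select
the PPG/ABP ensembles by upstroke and SNR, gate on participant-specific
SNR thresholds and a realistic PAT window, detect the PPG foot and SCG AO
point, compute PTT, fit the per-component calibration, and estimate BP.
Everything is deterministic given the session and the configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pttbp import beats as bt
from pttbp import quality as ql
from pttbp.calibrate import (
    BP_COMPONENTS,
    CalibrationError,
    CalibrationModel,
    CalibrationPoint,
    estimate_bp,
    fit_calibration,
)
from pttbp.fiducials import (
    DEFAULT_PEP_RANGE_S,
    DEFAULT_PROMINENCE_FRACTION,
    FiducialError,
    FiducialResult,
    compute_ptt,
    detect_ao,
    ppg_foot_intersecting_tangent,
)
from pttbp.preprocess import align_to_reference, detect_r_peaks, filter_session
from pttbp.session import Session, read_session
from pttbp.stats import AgreementReport, GroupComparison, agreement_metrics, compare_groups, ieee_grade

log = logging.getLogger("pttbp")


@dataclass
class RunConfig:
    """Tunable parameters of the full pipeline (defaults follow the study)."""

    wavelength: str = "ppg_ir"
    window_width: int = 10
    window_hop: int = 5
    snr_quantile: float = 0.25
    snr_overrides: dict = field(default_factory=dict)  # e.g. {"ppg_db": 10.0}
    foot_range_s: tuple[float, float] = (0.10, 0.50)
    #: beats this close to a task's start are excluded from windows, so
    #: hemodynamic transitions and filter transients at segment boundaries
    #: do not contaminate the ensembles
    task_guard_s: float = 1.0
    pep_range_s: tuple[float, float] = DEFAULT_PEP_RANGE_S
    ao_prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION
    consistent_ao: bool = False
    min_calibration_tasks: int = 4
    grade_thresholds: dict | None = None
    filter_bands: dict | None = None


@dataclass
class ParticipantResult:
    participant_id: str
    fiducials: pd.DataFrame  # task, wavelength, foot_s, ao_s, ptt_s, pat_s
    models: dict[str, CalibrationModel]
    estimates: pd.DataFrame  # task, ptt_s, est/ref per component
    qc: pd.DataFrame  # task, kept, reasons, snrs
    calibratable: bool
    lag_samples: int | None = None

    def agreement(self, component: str) -> AgreementReport:
        est = self.estimates[f"est_{component.lower()}"].to_numpy()
        ref = self.estimates[f"ref_{component.lower()}"].to_numpy()
        return agreement_metrics(est, ref, component=component)


def _task_selection(task_label, ppg_ens, scg_ens, abp_ens, config):
    """Select PPG (upstroke pool + SNR), its paired SCG window, and the
    max-SNR ABP window for one task."""
    idx_ppg = ql.select_ppg_ensemble(ppg_ens)
    idx_abp = ql.select_reference_bp(abp_ens)
    return ql.TaskSelection(
        task=task_label,
        ppg=ppg_ens[idx_ppg],
        scg=scg_ens[idx_ppg],  # paired: same window as the chosen PPG
        abp=abp_ens[idx_abp],
        wavelength=config.wavelength,
    )


def run_participant(session: Session, config: RunConfig | None = None) -> ParticipantResult:
    """Run the full chain on one session.

    Dropped tasks are logged with their reasons; if fewer than
    ``min_calibration_tasks`` survive, the participant is flagged
    uncalibratable (``calibratable=False``) and no models are fitted.
    """
    config = config or RunConfig()
    pid = session.demographics.participant_id
    fs = session.fs

    aligned = align_to_reference(session)
    filtered = filter_session(aligned, bands=config.filter_bands)
    r_times = detect_r_peaks(filtered.channel("ecg_wearable").samples, fs)

    channels_needed = [config.wavelength, "scg_z", "abp"]
    beatsets = {
        name: bt.segment_heartbeats(filtered.channel(name).samples, r_times, fs, channel=name)
        for name in channels_needed
    }

    tasks = filtered.tasks(measurement_only=True)
    per_task = []
    snr_pool: dict[str, list[float]] = {"ppg": [], "scg": [], "abp": []}
    for ann in tasks:
        ens = {}
        ok = True
        for name in channels_needed:
            task_beats = bt.beats_in_task(
                beatsets[name], ann.start_s + config.task_guard_s, ann.end_s
            )
            try:
                ens[name] = bt.ensemble_windows(task_beats, config.window_width, config.window_hop)
            except ValueError:
                ok = False
                break
            ql.score_ensembles(ens[name])
        if not ok:
            log.info("%s / %s: too few beats for one ensemble window", pid, ann.label)
            per_task.append((ann.label, None, ["too_few_beats"]))
            continue
        snr_pool["ppg"] += [e.snr_db for e in ens[config.wavelength]]
        snr_pool["scg"] += [e.snr_db for e in ens["scg_z"]]
        snr_pool["abp"] += [e.snr_db for e in ens["abp"]]
        sel = _task_selection(ann.label, ens[config.wavelength], ens["scg_z"], ens["abp"], config)
        per_task.append((ann.label, sel, []))

    # fiducials + gating (two passes when consistent-AO mode is on)
    def locate(sel, prefer_latency=None):
        foot = ppg_foot_intersecting_tangent(sel.ppg.samples, fs)
        ao = detect_ao(
            sel.scg.samples,
            fs,
            foot,
            pep_range_s=config.pep_range_s,
            prominence_fraction=config.ao_prominence_fraction,
            prefer_latency_s=prefer_latency,
        )
        return FiducialResult(
            foot_time_s=foot, ao_time_s=ao, wavelength=config.wavelength,
            pep_range_s=config.pep_range_s,
        )

    prefer = None
    if config.consistent_ao:
        first_pass = []
        for _, sel, pre_reasons in per_task:
            if sel is None or pre_reasons:
                continue
            try:
                first_pass.append(locate(sel).ao_time_s)
            except FiducialError:
                continue
        if first_pass:
            prefer = float(np.median(first_pass))

    located = []  # (label, selection, fiducial result or None, pre-drop reasons)
    for label, sel, pre_reasons in per_task:
        if sel is None:
            located.append((label, None, None, pre_reasons))
            continue
        try:
            located.append((label, sel, locate(sel, prefer_latency=prefer), []))
        except FiducialError as err:
            log.info("%s / %s: %s", pid, label, err)
            located.append((label, sel, None, ["fiducial"]))

    # participant-specific thresholds: start at the configured quantile of
    # the participant's own window SNRs and relax stepwise (never below the
    # absolute floors) until enough tasks survive to calibrate — the same
    # per-participant cutoff setting the study applied to retain at least
    # four tasks per participant
    quantile_ladder = [q for q in (config.snr_quantile, 0.15, 0.05, 0.0) if q <= config.snr_quantile]
    gated = None
    for q in quantile_ladder:
        thresholds = ql.participant_thresholds(
            snr_pool, quantile=q, foot_range_s=config.foot_range_s
        )
        for name, value in config.snr_overrides.items():
            setattr(thresholds, name, value)
        gated = [
            ql.gate_task(sel, thresholds, fid.foot_time_s).kept if fid is not None else False
            for _, sel, fid, _ in located
        ]
        if sum(gated) >= config.min_calibration_tasks:
            break

    qc_rows, fid_rows, cal_points = [], [], []
    for (label, sel, fid, pre_reasons), kept in zip(located, gated):
        if sel is None or fid is None:
            qc_rows.append({"task": label, "kept": False, "reasons": ",".join(pre_reasons),
                            "ppg_snr_db": sel.ppg.snr_db if sel else np.nan,
                            "scg_snr_db": sel.scg.snr_db if sel else np.nan,
                            "abp_snr_db": sel.abp.snr_db if sel else np.nan})
            continue
        qc_rows.append({"task": label, "kept": kept, "reasons": ",".join(sel.reasons),
                        "ppg_snr_db": sel.ppg.snr_db, "scg_snr_db": sel.scg.snr_db,
                        "abp_snr_db": sel.abp.snr_db})
        if not kept:
            log.info("%s / %s dropped: %s", pid, label, sel.reasons)
            continue
        ptt = compute_ptt(fid.ao_time_s, fid.foot_time_s)
        sbp, dbp, map_ = bt.abp_beat_bp(sel.abp)
        fid_rows.append({"task": label, "wavelength": config.wavelength,
                         "foot_s": fid.foot_time_s, "ao_s": fid.ao_time_s,
                         "ptt_s": ptt, "pat_s": fid.pat_s})
        cal_points.append(CalibrationPoint(task=label, ptt_s=ptt, dbp=dbp, map_=map_, sbp=sbp))

    fiducials = pd.DataFrame(fid_rows)
    qc = pd.DataFrame(qc_rows)

    models: dict[str, CalibrationModel] = {}
    calibratable = len(cal_points) >= config.min_calibration_tasks
    est_rows = []
    if calibratable:
        try:
            for c in BP_COMPONENTS:
                models[c] = fit_calibration(cal_points, c, min_points=config.min_calibration_tasks)
        except CalibrationError as err:
            log.warning("%s uncalibratable: %s", pid, err)
            calibratable = False
            models = {}
    if calibratable:
        for p in cal_points:
            row = {"task": p.task, "ptt_s": p.ptt_s}
            for c in BP_COMPONENTS:
                row[f"est_{c.lower()}"] = estimate_bp(models[c], p.ptt_s)
                row[f"ref_{c.lower()}"] = p.bp(c)
            est_rows.append(row)
    else:
        log.warning("%s flagged uncalibratable (%d tasks kept)", pid, len(cal_points))

    return ParticipantResult(
        participant_id=pid,
        fiducials=fiducials,
        models=models,
        estimates=pd.DataFrame(est_rows),
        qc=qc,
        calibratable=calibratable,
        lag_samples=aligned.alignment_lag_samples,
    )


@dataclass
class StudyReport:
    participants: list[ParticipantResult]
    agreement: dict[str, AgreementReport]
    grades: dict[str, str]
    comparisons: dict[tuple[str, str], GroupComparison]
    coefficients: pd.DataFrame

    @property
    def n_calibratable(self) -> int:
        return sum(p.calibratable for p in self.participants)


def coefficient_table(results: list[ParticipantResult], sessions: list[Session]) -> pd.DataFrame:
    """Per-participant calibration coefficients joined with demographics —
    the input to the demographic comparisons."""
    rows = []
    for res, sess in zip(results, sessions):
        if not res.calibratable:
            continue
        d = sess.demographics
        row = {"participant_id": res.participant_id, "age": d.age, "sex": d.sex,
               "race": d.race, "bmi": d.bmi, "obesity_class": d.obesity_class}
        for c, m in res.models.items():
            row[f"K1_{c}"] = m.k1
            row[f"K2_{c}"] = m.k2
        rows.append(row)
    return pd.DataFrame(rows)


def run_study(
    sessions: list[Session] | str | Path,
    config: RunConfig | None = None,
    groupings: tuple[str, ...] = ("obesity", "sex", "race", "age"),
    coefficients: tuple[str, ...] = ("K1_DBP", "K2_DBP"),
) -> StudyReport:
    """Process a cohort (a list of sessions or a directory of session files)
    and pool the agreement and demographic comparisons."""
    config = config or RunConfig()
    if not isinstance(sessions, list):
        directory = Path(sessions)
        paths = sorted(directory.glob("*.h5"))
        if not paths:
            raise FileNotFoundError(f"no session files (*.h5) in {directory}")
        sessions = [read_session(p) for p in paths]
    if not sessions:
        raise ValueError("no sessions given")

    results = [run_participant(s, config) for s in sessions]
    pooled = {c: ([], []) for c in BP_COMPONENTS}
    for res in results:
        if not res.calibratable:
            continue
        for c in BP_COMPONENTS:
            pooled[c][0].extend(res.estimates[f"est_{c.lower()}"])
            pooled[c][1].extend(res.estimates[f"ref_{c.lower()}"])
    agreement = {}
    grades = {}
    for c, (est, ref) in pooled.items():
        if len(est) >= 2:
            agreement[c] = agreement_metrics(est, ref, component=c)
            grades[c] = ieee_grade(agreement[c].mad, config.grade_thresholds)

    table = coefficient_table(results, sessions)
    comparisons = {}
    for grouping in groupings:
        for coef in coefficients:
            try:
                comparisons[(grouping, coef)] = compare_groups(table, grouping, coef)
            except ValueError as err:
                log.info("comparison %s/%s skipped: %s", grouping, coef, err)
    return StudyReport(
        participants=results,
        agreement=agreement,
        grades=grades,
        comparisons=comparisons,
        coefficients=table,
    )
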