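"""End-to-end orchestration: recording -> minute morphology -> session metrics,
and cohort table -> summary statistics + ROC analyses."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import diagnostics, morphology, pipeline
from .cohort import build_summary_table, scatter_export, subgroup_filter
from .config import DEFAULT_CONFIG, AnalysisConfig
from .errors import IcpwError, StageError
from .metrics import SessionMetrics, build_session_metrics, minute_icp_means, session_micp
from .pipeline import RawRecording

logger = logging.getLogger("icpw")


@dataclass
class RecordingAnalysis:
    """Per-minute morphology plus the session metrics of one recording."""

    minutes: pd.DataFrame  # minute, n_pulses, valid, p1_amp, p2_amp, p2p1, method
    metrics: SessionMetrics | None  # None when the ICP channel is absent
    session_p2p1: float
    n_valid_minutes: int
    qc: list[pipeline.MinuteQC]


def analyze_recording(
    rec: RawRecording, config: AnalysisConfig = DEFAULT_CONFIG
) -> RecordingAnalysis:
    """Full pulse pipeline on one recording.

    Band-pass filter, trough detection, beat segmentation, per-minute QC and
    ensemble averaging, then P1/P2 localization on each valid minute.  Session
    P2/P1 aggregates the per-minute ratios (mean by default); session mean ICP
    is computed from the raw co-recorded ICP channel when present.
    """

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except IcpwError as exc:
            raise StageError(name, exc) from exc

    filtered = stage("preprocess", pipeline.preprocess, rec)
    onsets = stage("detect_onsets", pipeline.detect_onsets, filtered, rec.fs_hz)
    segments = stage("segment_pulses", pipeline.segment_pulses, filtered, onsets, rec.fs_hz)
    segments, qc = stage(
        "filter_pulses",
        pipeline.filter_pulses,
        segments,
        min_correlation=config.qc_min_correlation,
        amplitude_band=config.qc_amplitude_band,
    )
    averages = stage(
        "average_by_minute",
        pipeline.average_by_minute,
        segments,
        min_pulses=config.min_pulses_per_minute,
    )

    recs = []
    minute_morphs = []
    for avg in averages:
        row = {"minute": avg.minute_index, "n_pulses": avg.n_pulses, "valid": avg.valid}
        if avg.valid:
            m = morphology.locate_peaks(avg, config)
            minute_morphs.append(m)
            row.update(
                p1_amp=m.p1_amp, p2_amp=m.p2_amp, p2p1=m.p2p1, method=m.method
            )
        else:
            logger.info("minute %d excluded by QC (%d accepted pulses)",
                        avg.minute_index, avg.n_pulses)
            row.update(p1_amp=np.nan, p2_amp=np.nan, p2p1=np.nan, method="")
        recs.append(row)

    sess_p2p1, n_valid = morphology.session_p2p1(
        minute_morphs, statistic=config.session_statistic
    )
    metrics = None
    if rec.icp_samples is not None:
        micp = session_micp(minute_icp_means(rec.icp_samples, rec.fs_hz))
        metrics = build_session_metrics(micp, sess_p2p1, n_valid, config)
    return RecordingAnalysis(
        minutes=pd.DataFrame(recs),
        metrics=metrics,
        session_p2p1=sess_p2p1,
        n_valid_minutes=n_valid,
        qc=qc,
    )


def cohort_report(
    patients: pd.DataFrame, config: AnalysisConfig = DEFAULT_CONFIG
) -> dict:
    """Summary table, ROC analyses and correlation for a cohort table.

    Produces: the stratified population summary; the mICP-P2/P1 Pearson
    correlation; AUROC (DeLong CI) and operating-point performance of P2/P1
    for intracranial hypertension; AUROC of P2/P1 and BCI for early death with
    a paired DeLong comparison; and, when neurosurgery status is present, the
    same analyses after excluding decompressive-craniectomy patients.
    """
    out: dict = {"n_patients": int(len(patients))}

    def _analyses(df: pd.DataFrame) -> dict:
        res: dict = {"n": int(len(df))}
        r, p = diagnostics.pearson_r(df["micp"], df["p2p1"])
        res["pearson_micp_p2p1"] = {"r": r, "p": p}
        labels = df["iht"].astype(int).to_numpy()
        if 0 < labels.sum() < len(labels):
            roc = diagnostics.delong_ci(df["p2p1"].to_numpy(), labels)
            perf = diagnostics.confusion_at_cutoff(
                df["p2p1"].to_numpy(), labels, config.p2p1_cutoff
            )
            res["p2p1_vs_iht"] = {"roc": asdict(roc), "at_cutoff": asdict(perf)}
        if "group" in df.columns:
            ed = (df["group"] == "ED").astype(int).to_numpy()
            if 0 < ed.sum() < len(ed):
                roc_p = diagnostics.delong_ci(df["p2p1"].to_numpy(), ed)
                roc_b = diagnostics.delong_ci(df["bci"].to_numpy(), ed)
                z, pz = diagnostics.delong_compare(
                    df["p2p1"].to_numpy(), df["bci"].to_numpy(), ed
                )
                res["early_death"] = {
                    "p2p1_roc": asdict(roc_p),
                    "bci_roc": asdict(roc_b),
                    "bci_at_cutoff": asdict(
                        diagnostics.confusion_at_cutoff(
                            df["bci"].to_numpy(), ed, config.bci_cutoff
                        )
                    ),
                    "delong_compare": {"z": z, "p": pz},
                }
        return res

    out["primary"] = _analyses(patients)
    if "group" in patients.columns and patients["group"].nunique() >= 2:
        out["summary_table"] = build_summary_table(patients).to_dataframe().to_dict(
            orient="records"
        )
    if "neurosurgery" in patients.columns:
        sub = subgroup_filter(patients, exclude_craniectomy=True)
        if len(sub) >= 3 and sub["iht"].nunique() > 1:
            out["craniectomy_excluded"] = _analyses(sub)
    out["scatter"] = scatter_export(patients).to_dict(orient="list")
    return out


def run_pipeline(
    config: AnalysisConfig = DEFAULT_CONFIG,
    recordings: list[RawRecording] | None = None,
    cohort: pd.DataFrame | None = None,
) -> dict:
    """Orchestrator: analyze any recordings, then report on the cohort table.

    Either input may be omitted; with only a cohort table the pulse stages are
    skipped.  Every random element downstream is seeded from ``config.seed``.
    """
    if not recordings and cohort is None:
        raise IcpwError("need at least one recording or a cohort table")
    report: dict = {"config_seed": config.seed}
    if recordings:
        sessions = []
        for i, rec in enumerate(recordings):
            ana = analyze_recording(rec, config)
            sessions.append(
                {
                    "recording": i,
                    "session_p2p1": ana.session_p2p1,
                    "n_valid_minutes": ana.n_valid_minutes,
                    "metrics": asdict(ana.metrics) if ana.metrics else None,
                    "qc": [asdict(q) for q in ana.qc],
                }
            )
        report["sessions"] = sessions
    if cohort is not None:
        df = subgroup_filter(cohort, config.exclude_craniectomy) \
            if config.exclude_craniectomy else cohort
        report["cohort"] = cohort_report(df, config)
    return report
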