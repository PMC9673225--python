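"""Per-session summary metrics: mean ICP, P2/P1, BCI, and threshold flags.

The brain compliance index (BCI) is the product mICP x P2/P1 (mmHg scale).
Session mean ICP is the mean of per-minute ICP means; intracranial
hypertension is strictly mICP > 20 mmHg, poor compliance strictly P2/P1 > 1.2,
high BCI strictly BCI > 19.3 — boundary values classify negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_CONFIG, AnalysisConfig
from .errors import InvalidParameterError

STO_GROUPS = ("SB", "MV", "ED")  # spontaneous breathing / ventilated / early death


@dataclass(frozen=True)
class SessionMetrics:
    micp: float
    p2p1: float
    bci: float
    iht: bool
    p2p1_high: bool
    bci_high: bool
    n_valid_minutes: int

    def __post_init__(self) -> None:
        if not math.isclose(self.bci, self.micp * self.p2p1, rel_tol=1e-12, abs_tol=1e-12):
            raise InvalidParameterError("bci must equal micp * p2p1")


@dataclass(frozen=True)
class PatientRecord:
    id: str
    group: str
    metrics: SessionMetrics
    age: float | None = None
    sex: str | None = None
    pathology: str | None = None
    neurosurgery: str | None = None  # none / craniotomy / craniectomy

    def __post_init__(self) -> None:
        if self.group not in STO_GROUPS:
            raise InvalidParameterError(
                f"group must be one of {STO_GROUPS}, got {self.group!r}"
            )


def minute_icp_means(icp_samples: np.ndarray, fs_hz: float) -> np.ndarray:
    """Mean invasive ICP of each full or partial minute of the recording."""
    icp = np.asarray(icp_samples, dtype=float)
    if len(icp) == 0:
        raise InvalidParameterError("empty ICP channel")
    per_min = int(round(60 * fs_hz))
    n_minutes = int(np.ceil(len(icp) / per_min))
    return np.array(
        [icp[m * per_min : (m + 1) * per_min].mean() for m in range(n_minutes)]
    )


def session_micp(minute_means) -> float:
    """Session mean ICP: the average of the per-minute means."""
    means = np.asarray(list(minute_means), dtype=float)
    if means.size == 0:
        raise InvalidParameterError("need at least one minute mean")
    return float(means.mean())


def compute_bci(micp: float, p2p1: float) -> float:
    """Brain compliance index: mICP x P2/P1 (mmHg)."""
    if micp < 0:
        raise InvalidParameterError(f"micp must be >= 0, got {micp}")
    if p2p1 <= 0:
        raise InvalidParameterError(f"p2p1 must be > 0, got {p2p1}")
    return micp * p2p1


def classify(
    micp: float,
    p2p1: float,
    bci: float,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> dict[str, bool]:
    """Strict-inequality threshold flags for IHT, high P2/P1 and high BCI."""
    for name, v in (("micp", micp), ("p2p1", p2p1), ("bci", bci)):
        if not math.isfinite(v):
            raise InvalidParameterError(f"{name} must be finite, got {v}")
    return {
        "iht": micp > config.iht_cutoff_mmhg,
        "p2p1_high": p2p1 > config.p2p1_cutoff,
        "bci_high": bci > config.bci_cutoff,
    }


def build_session_metrics(
    micp: float,
    p2p1: float,
    n_valid_minutes: int,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> SessionMetrics:
    bci = compute_bci(micp, p2p1)
    flags = classify(micp, p2p1, bci, config)
    return SessionMetrics(
        micp=micp,
        p2p1=p2p1,
        bci=bci,
        n_valid_minutes=n_valid_minutes,
        **flags,
    )
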