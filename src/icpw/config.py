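"""Analysis configuration: every clinical cutoff and pipeline default in one place.

The three clinical thresholds (mean ICP > 20 mmHg for intracranial
hypertension, P2/P1 > 1.2 for poor compliance, BCI > 19.3) are strict
inequalities; boundary values classify negative.  Quality-control limits and
peak-search windows are analysis defaults exposed for sensitivity analyses.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from .errors import InvalidParameterError


@dataclass(frozen=True)
class AnalysisConfig:
    # clinical cutoffs (strict '>' everywhere)
    iht_cutoff_mmhg: float = 20.0
    p2p1_cutoff: float = 1.2
    bci_cutoff: float = 19.3

    # pulse quality control
    qc_min_correlation: float = 0.8
    qc_amplitude_band: tuple[float, float] = (0.3, 3.0)
    min_pulses_per_minute: int = 30

    # peak-search windows, as fractions of the cardiac cycle
    p1_window: tuple[float, float] = (0.05, 0.28)
    p2_window: tuple[float, float] = (0.28, 0.60)
    p3_window: tuple[float, float] = (0.60, 0.90)

    # session aggregation statistic for per-minute P2/P1 values
    session_statistic: str = "mean"  # "mean" or "median"

    # cohort handling
    exclude_craniectomy: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("iht_cutoff_mmhg", "p2p1_cutoff", "bci_cutoff"):
            v = getattr(self, name)
            if not (v == v and abs(v) != float("inf")):
                raise InvalidParameterError(f"{name} must be finite, got {v!r}")
        for name in ("p1_window", "p2_window", "p3_window", "qc_amplitude_band"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise InvalidParameterError(f"{name} must be ordered, got ({lo}, {hi})")
        if self.session_statistic not in ("mean", "median"):
            raise InvalidParameterError(
                f"session_statistic must be 'mean' or 'median', got {self.session_statistic!r}"
            )
        if self.min_pulses_per_minute < 1:
            raise InvalidParameterError("min_pulses_per_minute must be >= 1")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        for key in ("qc_amplitude_band", "p1_window", "p2_window", "p3_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


DEFAULT_CONFIG = AnalysisConfig()
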