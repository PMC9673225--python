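"""P1/P2(/P3) localization on an averaged ICP-like pulse and the P2/P1 ratio.

A cardiac ICP pulse carries three sub-peaks: P1 (percussion wave, arterial
ejection), P2 (tidal wave, blood-volume spreading) and P3 (dicrotic wave).
As intracranial compliance worsens, P2 grows relative to P1, so the P2/P1
amplitude ratio is the morphology statistic of interest.  Amplitudes are
measured above the onset-trough baseline (the first sample of the averaged
pulse), which makes the ratio invariant to gain and offset of the raw sensor
signal.

Peak search uses fixed latency windows on the normalized cycle — P1 in
[0.05, 0.28], P2 in (0.28, 0.60], P3 in (0.60, 0.90] — reflecting the
physiological ordering of the percussion and tidal waves.  When a window
holds no local maximum (peaks merged into a shoulder), a fallback locates the
shoulder as a zero-crossing of the smoothed second derivative; if that also
fails, the window maximum is used and the result flagged low-confidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_CONFIG, AnalysisConfig
from .errors import InvalidParameterError, UndefinedRatioError
from .pipeline import AveragedPulse

METHOD_TWO_PEAKS = "two-peaks"
METHOD_SHOULDER = "shoulder"
METHOD_MERGED = "merged-fallback"

_METHOD_RANK = {METHOD_TWO_PEAKS: 0, METHOD_SHOULDER: 1, METHOD_MERGED: 2}


@dataclass(frozen=True)
class PulseMorphology:
    """Located peak amplitudes/latencies and the P2/P1 ratio of one pulse.

    Amplitudes are relative to the onset-trough baseline; latencies are
    fractions of the cardiac cycle.  ``method`` records whether both peaks
    were true local maxima, a shoulder rule was needed, or a low-confidence
    window-maximum fallback was used.  ``time_to_peak`` (latency of the global
    maximum) is reported for completeness but feeds no downstream index.
    """

    p1_amp: float
    p2_amp: float
    p1_lat: float
    p2_lat: float
    p2p1: float
    method: str
    p3_amp: float | None = None
    p3_lat: float | None = None
    time_to_peak: float | None = None
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if not self.p1_lat < self.p2_lat:
            raise InvalidParameterError("p1_lat must precede p2_lat")
        if self.p1_amp < 0 or self.p2_amp < 0:
            raise InvalidParameterError("amplitudes must be >= 0")


def _local_maxima(y: np.ndarray) -> np.ndarray:
    """Indices of strict-left / non-strict-right interior local maxima."""
    d = np.diff(y)
    return np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0)) + 1


def _shoulder_candidates(y: np.ndarray, smooth: int = 5) -> np.ndarray:
    """Zero-crossings of the second derivative after a short moving average."""
    kernel = np.ones(smooth) / smooth
    ys = np.convolve(y, kernel, mode="same")
    d2 = np.gradient(np.gradient(ys))
    sign = np.sign(d2)
    crossings = np.flatnonzero(np.diff(sign) != 0)
    return crossings


def _find_in_window(
    u: np.ndarray, y: np.ndarray, window: tuple[float, float]
) -> tuple[int, str]:
    """Best peak index in a latency window and the detection method used."""
    lo, hi = window
    in_win = (u > lo) & (u <= hi) if lo > 0 else (u >= lo) & (u <= hi)
    win_idx = np.flatnonzero(in_win)
    if len(win_idx) == 0:
        raise InvalidParameterError(f"window {window} holds no samples")

    maxima = [i for i in _local_maxima(y) if in_win[i]]
    if maxima:
        vals = y[maxima]
        best = maxima[int(np.argmax(vals))]
        # ties between equal maxima: earliest wins (argmax already returns first)
        return best, METHOD_TWO_PEAKS

    shoulders = [i for i in _shoulder_candidates(y) if in_win[i]]
    if shoulders:
        best = shoulders[int(np.argmax(y[shoulders]))]
        return best, METHOD_SHOULDER

    best = win_idx[int(np.argmax(y[win_idx]))]
    return best, METHOD_MERGED


def locate_peaks(
    avg: AveragedPulse, config: AnalysisConfig = DEFAULT_CONFIG
) -> PulseMorphology:
    """Locate P1, P2 and P3 on a valid averaged pulse and form P2/P1."""
    if not isinstance(avg, AveragedPulse):
        avg = AveragedPulse(
            minute_index=0,
            n_pulses=1,
            samples=np.asarray(avg, dtype=float),
            valid=True,
        )
    if not avg.valid:
        raise InvalidParameterError("averaged pulse is not valid (too few beats)")
    y = np.asarray(avg.samples, dtype=float)
    n = len(y)
    u = np.arange(n) / n
    baseline = y[0]

    i1, m1 = _find_in_window(u, y, config.p1_window)
    i2, m2 = _find_in_window(u, y, config.p2_window)
    method = max(m1, m2, key=lambda m: _METHOD_RANK[m])

    p1_amp = float(y[i1] - baseline)
    p2_amp = float(y[i2] - baseline)
    if p1_amp <= 0:
        raise UndefinedRatioError(
            f"P1 amplitude is {p1_amp:.4g}; P2/P1 is undefined"
        )
    p2_amp = max(p2_amp, 0.0)

    try:
        i3, _ = _find_in_window(u, y, config.p3_window)
        p3_amp: float | None = max(float(y[i3] - baseline), 0.0)
        p3_lat: float | None = float(u[i3])
    except InvalidParameterError:
        p3_amp = p3_lat = None

    return PulseMorphology(
        p1_amp=p1_amp,
        p2_amp=p2_amp,
        p1_lat=float(u[i1]),
        p2_lat=float(u[i2]),
        p2p1=p2_amp / p1_amp,
        method=method,
        p3_amp=p3_amp,
        p3_lat=p3_lat,
        time_to_peak=float(u[int(np.argmax(y))]),
        low_confidence=method == METHOD_MERGED,
    )


def p2p1_ratio(morph: PulseMorphology) -> float:
    """P2 amplitude divided by P1 amplitude."""
    if morph.p1_amp <= 0:
        raise UndefinedRatioError("P1 amplitude must be > 0")
    return morph.p2_amp / morph.p1_amp


def session_p2p1(
    minute_morphs: list[PulseMorphology],
    statistic: str = "mean",
) -> tuple[float, int]:
    """Session-level P2/P1: mean (default) or median of per-minute ratios.

    Returns the aggregate and the number of contributing minutes.
    """
    ratios = [m.p2p1 for m in minute_morphs if m is not None]
    if not ratios:
        raise InvalidParameterError("no valid minutes: session P2/P1 undefined")
    agg = float(np.mean(ratios)) if statistic == "mean" else float(np.median(ratios))
    return agg, len(ratios)
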