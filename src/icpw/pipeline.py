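"""From raw pulsatile recording to per-minute ensemble-averaged pulses.

The cranial-deformation signal is recorded in arbitrary units, so every step
here is scale-free: band-pass filtering is linear, beat detection uses only
relative extrema, and quality control compares each beat with the median beat
of its minute by correlation and relative amplitude.  Beats are delimited
trough-to-trough (the onset trough is the natural amplitude baseline for peak
measurements), time-normalized to a fixed 100-point base, and averaged within
each minute of monitoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import InvalidParameterError, NoPulsesError

PULSE_NPOINTS = 100  # common normalized time base (1% of cycle per point)

BAND_LOW_HZ = 0.5
BAND_HIGH_HZ = 15.0

# physiologic beat-period band: 30-180 bpm
MIN_BEAT_PERIOD_S = 0.33
MAX_BEAT_PERIOD_S = 2.0


@dataclass
class RawRecording:
    """A sampled single-channel pulsatile signal, optionally with invasive ICP.

    ``samples`` are in arbitrary sensor units; ``icp_samples``, when present,
    is the co-recorded invasive ICP in mmHg on the same time base.
    """

    samples: np.ndarray
    fs_hz: float
    icp_samples: np.ndarray | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise InvalidParameterError(f"fs_hz must be > 0, got {self.fs_hz}")
        if self.icp_samples is not None:
            self.icp_samples = np.asarray(self.icp_samples, dtype=float)
            if len(self.icp_samples) != len(self.samples):
                raise InvalidParameterError(
                    "icp_samples must have the same length as samples"
                )

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz


@dataclass
class PulseSegment:
    """One beat, delimited by consecutive onset troughs [onset_idx, end_idx)."""

    minute_index: int
    onset_idx: int
    end_idx: int
    samples: np.ndarray
    resampled: np.ndarray | None = None  # on the 100-point base, filled by QC
    quality: float = np.nan  # correlation with the minute's median pulse
    accepted: bool = False

    def __post_init__(self) -> None:
        if self.end_idx <= self.onset_idx:
            raise InvalidParameterError("end_idx must exceed onset_idx")
        if self.minute_index < 0:
            raise InvalidParameterError("minute_index must be >= 0")


@dataclass
class AveragedPulse:
    """Ensemble mean of the accepted beats of one minute, on the 100-point base."""

    minute_index: int
    n_pulses: int
    samples: np.ndarray
    valid: bool

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if len(self.samples) != PULSE_NPOINTS:
            raise InvalidParameterError(
                f"averaged pulse must have {PULSE_NPOINTS} samples"
            )


@dataclass
class MinuteQC:
    minute_index: int
    n_total: int
    n_accepted: int
    n_rejected: int


def preprocess(rec: RawRecording) -> np.ndarray:
    """Zero-phase 0.5-15 Hz band-pass of the raw signal (length preserved).

    Removes baseline wander (respiratory drift and DC) below the cardiac band
    and high-frequency noise above it, without phase distortion, so trough and
    peak positions are not shifted systematically by filter delay.
    """
    x = np.asarray(rec.samples, dtype=float)
    if len(x) < 2 * rec.fs_hz:
        raise InvalidParameterError("need at least 2 s of signal to filter")
    if rec.fs_hz < 2 * BAND_HIGH_HZ:
        raise InvalidParameterError(
            f"fs_hz must be >= {2 * BAND_HIGH_HZ} Hz for a {BAND_HIGH_HZ} Hz band edge"
        )
    sos = sps.butter(
        4, [BAND_LOW_HZ, BAND_HIGH_HZ], btype="bandpass", fs=rec.fs_hz, output="sos"
    )
    return sps.sosfiltfilt(sos, x)


def estimate_beat_period(filtered: np.ndarray, fs_hz: float) -> float:
    """Beat period from the dominant autocorrelation peak in the 0.33-2 s band."""
    x = np.asarray(filtered, dtype=float)
    x = x - x.mean()
    n = len(x)
    lo = int(np.ceil(MIN_BEAT_PERIOD_S * fs_hz))
    hi = min(int(np.floor(MAX_BEAT_PERIOD_S * fs_hz)), n - 1)
    if hi <= lo or not np.any(x):
        raise NoPulsesError("no pulsatile activity: signal too short or flat")
    # FFT autocorrelation
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec), nfft)[: n]
    band = ac[lo : hi + 1]
    if band.max() <= 0:
        raise NoPulsesError("no autocorrelation peak in the physiologic beat band")
    # the autocorrelation also peaks at every multiple of the beat period;
    # take the earliest local maximum comparable to the band maximum rather
    # than the global argmax, which can lock onto a harmonic
    peaks, _ = sps.find_peaks(band, height=0.75 * band.max())
    return (lo + (int(peaks[0]) if len(peaks) else int(np.argmax(band)))) / fs_hz


def detect_onsets(filtered: np.ndarray, fs_hz: float) -> np.ndarray:
    """Pulse-onset sample indices (the foot of each beat's upstroke).

    The expected beat period is first estimated from the autocorrelation peak
    in the 0.33-2 s lag band and sets an adaptive refractory window of 0.6x
    that period.  One anchor per beat is placed at the systolic max-upslope
    point (the dominant first-derivative peak); the onset is then refined
    backwards to the point of maximal curvature — the corner of the onset
    trough, which a 15 Hz low-pass shifts far less than the trough minimum
    itself.  Final onsets are local waveform feet separated by at least
    max(0.33 s, 0.6 x period) and at most one per beat.
    """
    x = np.asarray(filtered, dtype=float)
    if len(x) < 5 * fs_hz:
        raise NoPulsesError("need at least 5 s of signal for onset detection")
    period = estimate_beat_period(x, fs_hz)
    d1 = np.gradient(x)
    sd1 = float(np.std(d1))
    if sd1 == 0:
        raise NoPulsesError("flat signal: no pulses")
    dist = max(1, int(round(0.6 * period * fs_hz)))
    anchors, _ = sps.find_peaks(d1, distance=dist, prominence=0.5 * sd1)
    if len(anchors) == 0:
        raise NoPulsesError("no pulse upstrokes found")
    d2 = np.gradient(d1)
    back = max(2, int(round(0.35 * period * fs_hz)))
    onsets = []
    for k in anchors:
        a = k - back
        if a >= 0:
            onsets.append(a + int(np.argmax(d2[a : k + 1])))
        else:
            # window clipped by the recording start: the beat began at or
            # before sample 0 if the signal is still rising there — walk back
            # along the upstroke and clamp at 0
            nonpos = np.flatnonzero(d1[: k + 1] <= 0)
            onsets.append(int(nonpos[-1]) + 1 if len(nonpos) else 0)
    onsets = np.unique(onsets)
    # refractory pass: enforce the minimum physiologic separation
    min_sep = max(MIN_BEAT_PERIOD_S, 0.6 * period) * fs_hz
    kept = [int(onsets[0])]
    for o in onsets[1:]:
        if o - kept[-1] >= min_sep:
            kept.append(int(o))
    return np.asarray(kept, dtype=int)


def segment_pulses(
    filtered: np.ndarray, onsets: np.ndarray, fs_hz: float
) -> list[PulseSegment]:
    """One segment per consecutive onset pair; the trailing partial beat is dropped.

    Each segment is assigned to the minute containing its onset.
    """
    onsets = np.asarray(onsets, dtype=int)
    if len(onsets) < 2:
        raise InvalidParameterError("need at least 2 onsets to segment")
    segs: list[PulseSegment] = []
    for a, b in zip(onsets[:-1], onsets[1:]):
        minute = int((a / fs_hz) // 60)
        segs.append(
            PulseSegment(
                minute_index=minute,
                onset_idx=int(a),
                end_idx=int(b),
                samples=np.asarray(filtered[a:b], dtype=float),
            )
        )
    return segs


def resample_segment(seg_samples: np.ndarray, n: int = PULSE_NPOINTS) -> np.ndarray:
    """Time-normalize one beat to ``n`` points covering [0, 1) of its cycle."""
    m = len(seg_samples)
    u = np.arange(n) / n
    return np.interp(u, np.arange(m) / m, seg_samples)


def filter_pulses(
    segments: list[PulseSegment],
    min_correlation: float = 0.8,
    amplitude_band: tuple[float, float] = (0.3, 3.0),
) -> tuple[list[PulseSegment], list[MinuteQC]]:
    """Flag beats as accepted/rejected against their minute's median pulse.

    Each beat is resampled to the 100-point base and compared with the
    pointwise-median pulse of its minute: accepted iff Pearson correlation
    >= ``min_correlation`` AND its peak-to-trough amplitude lies within
    ``amplitude_band`` times the minute's median amplitude.  A minute with a
    single beat accepts it by convention (the beat is its own median).
    """
    if not segments:
        raise InvalidParameterError("no segments to filter")
    by_minute: dict[int, list[PulseSegment]] = {}
    for s in segments:
        s.resampled = resample_segment(s.samples)
        by_minute.setdefault(s.minute_index, []).append(s)

    qc: list[MinuteQC] = []
    for minute, segs in sorted(by_minute.items()):
        mat = np.vstack([s.resampled for s in segs])
        median_pulse = np.median(mat, axis=0)
        amplitudes = mat.max(axis=1) - mat.min(axis=1)
        med_amp = float(np.median(amplitudes))
        n_acc = 0
        for s, amp in zip(segs, amplitudes):
            r = _safe_corr(s.resampled, median_pulse)
            s.quality = r
            amp_ok = (
                med_amp > 0
                and amplitude_band[0] * med_amp <= amp <= amplitude_band[1] * med_amp
            )
            if len(segs) == 1:
                s.accepted = True
            else:
                s.accepted = (r >= min_correlation) and amp_ok
            n_acc += int(s.accepted)
        qc.append(
            MinuteQC(
                minute_index=minute,
                n_total=len(segs),
                n_accepted=n_acc,
                n_rejected=len(segs) - n_acc,
            )
        )
    return segments, qc


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def average_by_minute(
    segments: list[PulseSegment], min_pulses: int = 30
) -> list[AveragedPulse]:
    """Pointwise mean of the accepted beats of each minute.

    A minute with fewer than ``min_pulses`` accepted beats (default 30) is
    returned with ``valid=False`` rather than raising, so session aggregation
    can simply skip it.
    """
    by_minute: dict[int, list[PulseSegment]] = {}
    for s in segments:
        by_minute.setdefault(s.minute_index, []).append(s)
    out: list[AveragedPulse] = []
    for minute in range(max(by_minute) + 1 if by_minute else 0):
        segs = [s for s in by_minute.get(minute, []) if s.accepted]
        if segs:
            for s in segs:
                if s.resampled is None:
                    s.resampled = resample_segment(s.samples)
            mean_pulse = np.mean(np.vstack([s.resampled for s in segs]), axis=0)
        else:
            mean_pulse = np.zeros(PULSE_NPOINTS)
        out.append(
            AveragedPulse(
                minute_index=minute,
                n_pulses=len(segs),
                samples=mean_pulse,
                valid=len(segs) >= min_pulses,
            )
        )
    return out
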