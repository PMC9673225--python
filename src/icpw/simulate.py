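"""Synthetic cranial-deformation waveforms and patient cohorts with ground truth.

The study data this package analyzes (10-minute bedside recordings of a
noninvasive cranial-deformation sensor co-recorded with invasive ICP) are not
publicly deposited, so this module generates physiologically plausible
stand-ins with known ground truth:

* a single cardiac pulse as the sum of three Gaussian components standing for
  the percussion (P1), tidal (P2) and dicrotic (P3) waves — the P2/P1 ratio of
  the summed curve rises as the tidal component grows, emulating worsening
  intracranial compliance;
* a session-length recording: beats concatenated with heart-rate jitter,
  respiratory baseline drift, additive white noise, occasional high-amplitude
  motion artifacts, and a co-recorded invasive ICP channel in mmHg;
* a binormal score model calibrated so that the P2/P1-vs-hypertension
  operating characteristics (AUROC, sensitivity and specificity at the 1.2
  cutoff) match chosen targets;
* a patient cohort whose mean-ICP distribution matches quartile targets and
  whose linear ICP-to-P2/P1 link reproduces a chosen correlation.

Everything is reproducible: each entry point takes a seed and uses one local
generator; there is no global RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

from .errors import CalibrationInfeasibleError, InvalidParameterError
from .morphology import (
    METHOD_MERGED,
    METHOD_SHOULDER,
    METHOD_TWO_PEAKS,
    PulseMorphology,
)
from .pipeline import RawRecording

_METHOD_RANK = {METHOD_TWO_PEAKS: 0, METHOD_SHOULDER: 1, METHOD_MERGED: 2}

# peak-search windows on the normalized cycle (kept numerically identical to
# the analysis defaults so "achieved" ground truth and estimates are comparable)
P1_WINDOW = (0.05, 0.28)
P2_WINDOW = (0.28, 0.60)


# --------------------------------------------------------------------------
# pulse shape
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PulseShapeParams:
    """Three-Gaussian cardiac pulse template.

    Latencies and widths are fractions of the pulse duration; amplitudes are
    arbitrary units.  The summed curve — not the component amplitudes — defines
    the achieved P2/P1 ground truth, because overlapping components shift the
    extrema that any peak detector (including ours) actually sees.
    """

    amp1: float = 1.0
    amp2: float = 1.12
    amp3: float = 0.65
    lat1: float = 0.13
    lat2: float = 0.40
    lat3: float = 0.70
    width1: float = 0.07
    width2: float = 0.12
    width3: float = 0.16
    pulse_duration: float = 0.85

    def __post_init__(self) -> None:
        if not (self.lat1 < self.lat2 < self.lat3):
            raise InvalidParameterError(
                f"latencies must be strictly increasing, got "
                f"({self.lat1}, {self.lat2}, {self.lat3})"
            )
        for name in ("lat1", "lat2", "lat3"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise InvalidParameterError(f"{name} must lie in (0, 1), got {v}")
        for name in ("width1", "width2", "width3"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        for name in ("amp1", "amp2", "amp3"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.pulse_duration <= 0:
            raise InvalidParameterError("pulse_duration must be > 0")

    def evaluate(self, u: np.ndarray) -> np.ndarray:
        """Sum of the three Gaussian components at cycle fractions ``u``."""
        u = np.asarray(u, dtype=float)
        y = np.zeros_like(u)
        for amp, lat, width in (
            (self.amp1, self.lat1, self.width1),
            (self.amp2, self.lat2, self.width2),
            (self.amp3, self.lat3, self.width3),
        ):
            if amp > 0:
                y = y + amp * np.exp(-((u - lat) ** 2) / (2 * width**2))
        return y


DEFAULT_SHAPE = PulseShapeParams()


def achieved_morphology(
    shape: PulseShapeParams, n_grid: int = 100_000
) -> PulseMorphology:
    """Ground-truth morphology of the noiseless template on a dense grid.

    Evaluates the analytic three-Gaussian sum on ``n_grid`` points of the
    cycle and reads P1/P2 off the summed curve inside the standard latency
    windows: highest local maximum, else second-derivative zero-crossing
    (shoulder), else window maximum (merged fallback, flagged).
    """
    u = np.arange(n_grid) / n_grid
    y = shape.evaluate(u)
    baseline = y[0]

    def pick(window: tuple[float, float], strict_left: bool) -> tuple[int, str]:
        lo, hi = window
        in_win = ((u > lo) if strict_left else (u >= lo)) & (u <= hi)
        d = np.diff(y)
        maxima = np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0)) + 1
        maxima = maxima[in_win[maxima]]
        if len(maxima):
            return int(maxima[np.argmax(y[maxima])]), METHOD_TWO_PEAKS
        d2 = np.gradient(np.gradient(y))
        crossings = np.flatnonzero(np.diff(np.sign(d2)) != 0)
        crossings = crossings[in_win[crossings]]
        if len(crossings):
            return int(crossings[np.argmax(y[crossings])]), METHOD_SHOULDER
        win = np.flatnonzero(in_win)
        return int(win[np.argmax(y[win])]), METHOD_MERGED

    i1, m1 = pick(P1_WINDOW, strict_left=False)
    i2, m2 = pick(P2_WINDOW, strict_left=True)
    method = max(m1, m2, key=lambda m: _METHOD_RANK[m])
    p1_amp = float(y[i1] - baseline)
    p2_amp = max(float(y[i2] - baseline), 0.0)
    if p1_amp <= 0:
        raise InvalidParameterError("degenerate shape: no P1 amplitude")
    return PulseMorphology(
        p1_amp=p1_amp,
        p2_amp=p2_amp,
        p1_lat=float(u[i1]),
        p2_lat=float(u[i2]),
        p2p1=p2_amp / p1_amp,
        method=method,
        time_to_peak=float(u[int(np.argmax(y))]),
        low_confidence=method == METHOD_MERGED,
    )


def simulate_pulse(
    shape: PulseShapeParams, fs_hz: float
) -> tuple[np.ndarray, PulseMorphology]:
    """Sample the noiseless template at ``fs_hz`` and return its ground truth.

    The returned morphology is the *achieved* one — peaks of the summed curve
    on a dense grid — which is what any detector sees, not the component
    amplitudes.
    """
    n = int(round(fs_hz * shape.pulse_duration))
    if n < 20:
        raise InvalidParameterError(
            "fs_hz * pulse_duration must give at least 20 samples"
        )
    u = np.arange(n) / n
    return shape.evaluate(u), achieved_morphology(shape)


def shape_with_ratio(
    target_p2p1: float, base: PulseShapeParams = DEFAULT_SHAPE
) -> PulseShapeParams:
    """Adjust the tidal-component amplitude so the achieved ratio hits a target.

    Worsening compliance is emulated purely through amp2; latencies and widths
    stay at the template defaults.
    """

    def f(a2: float) -> float:
        return achieved_morphology(replace(base, amp2=a2), n_grid=20_000).p2p1 - target_p2p1

    lo, hi = 1e-3, 6.0
    if f(lo) > 0 or f(hi) < 0:
        raise InvalidParameterError(
            f"target ratio {target_p2p1} unreachable by varying amp2 in [{lo}, {hi}]"
        )
    a2 = optimize.brentq(f, lo, hi, xtol=1e-6)
    return replace(base, amp2=float(a2))


# --------------------------------------------------------------------------
# session recording
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SessionSimParams:
    """One simulated 10-minute monitoring session (defaults emulate the study).

    A session is at least ~700 heart beats: 600 s at 72 bpm nominal heart
    rate.  Noise terms are arbitrary units on a template of unit P1 amplitude;
    drift sits in the respiratory band and is removed by the analysis
    band-pass.  ``micp_mmhg`` drives the co-recorded invasive ICP channel.
    """

    shape: PulseShapeParams = DEFAULT_SHAPE
    heart_rate_bpm: float = 72.0
    hr_jitter_frac: float = 0.02
    drift_amp: float = 0.3
    drift_freq_hz: float = 0.25
    noise_sd: float = 0.05
    artifact_rate_per_min: float = 0.5
    duration_s: float = 600.0
    fs_hz: float = 200.0
    micp_mmhg: float = 14.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 20 < self.heart_rate_bpm < 220:
            raise InvalidParameterError("heart_rate_bpm must be in (20, 220)")
        if self.duration_s <= 0:
            raise InvalidParameterError("duration_s must be > 0")
        if self.fs_hz < 50:
            raise InvalidParameterError("fs_hz must be >= 50")
        for name in ("hr_jitter_frac", "drift_amp", "noise_sd", "artifact_rate_per_min"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.duration_s < 60.0 / self.heart_rate_bpm:
            raise InvalidParameterError("duration too short for a single beat")


@dataclass
class GroundTruth:
    """What the generator actually produced, for recovery tests."""

    onsets: np.ndarray  # true pulse-onset times, seconds, strictly increasing
    true_p2p1: float  # achieved ratio of the noiseless template
    true_micp: float  # mmHg
    artifact_windows: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if np.any(np.diff(self.onsets) <= 0):
            raise InvalidParameterError("onsets must be strictly increasing")
        if self.true_p2p1 <= 0:
            raise InvalidParameterError("true_p2p1 must be > 0")


ARTIFACT_DURATION_S = 0.3
ARTIFACT_GAIN = 5.0  # times the clean peak-to-trough amplitude
ICP_PULSE_AMP_MMHG = 3.0
ICP_NOISE_SD_MMHG = 0.2


def simulate_recording(
    params: SessionSimParams,
) -> tuple[RawRecording, GroundTruth]:
    """Concatenated-beat recording with drift, noise, artifacts and ICP channel.

    Beat ``i`` lasts 60/HR_i seconds where HR_i has the configured relative
    jitter; within each beat the template is evaluated on fractional time, so
    every beat has the template's shape regardless of its duration.  The
    template rises from its onset and is still decaying at the beat end, which
    puts the true waveform minimum exactly at each beat boundary — the
    quantity trough-to-trough onset detection estimates.

    Motion artifacts are 0.3-s half-sine transients of 5x the clean
    peak-to-trough amplitude at Poisson-distributed times.  The invasive ICP
    channel is true mean ICP plus a mean-zero scaled copy of the clean pulse
    train (3 mmHg peak-to-trough) plus measurement noise, so per-minute ICP
    means recover ``micp_mmhg``.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.fs_hz
    n = int(round(params.duration_s * fs))
    t = np.arange(n) / fs

    # beat onsets: accumulate jittered beat durations until the session ends
    onsets: list[float] = []
    durations: list[float] = []
    tc = 0.0
    while tc < params.duration_s - 1e-9:
        onsets.append(tc)
        hr_i = params.heart_rate_bpm * (
            1.0 + params.hr_jitter_frac * rng.standard_normal()
        )
        hr_i = float(np.clip(hr_i, 20.1, 219.9))
        dur = 60.0 / hr_i
        durations.append(dur)
        tc += dur

    clean = np.zeros(n)
    for onset, dur in zip(onsets, durations):
        i0 = int(np.ceil(onset * fs - 1e-9))
        i1 = min(int(np.ceil((onset + dur) * fs - 1e-9)), n)
        if i1 <= i0:
            continue
        u = (t[i0:i1] - onset) / dur
        clean[i0:i1] = params.shape.evaluate(u)

    drift = params.drift_amp * np.sin(2 * np.pi * params.drift_freq_hz * t)
    noise = rng.normal(0.0, params.noise_sd, n) if params.noise_sd > 0 else np.zeros(n)

    signal = clean + drift + noise

    # motion artifacts
    artifact_windows: list[tuple[float, float]] = []
    expected = params.artifact_rate_per_min * params.duration_s / 60.0
    n_artifacts = int(rng.poisson(expected)) if expected > 0 else 0
    ptp = float(clean.max() - clean.min()) or 1.0
    for _ in range(n_artifacts):
        start = float(rng.uniform(0.0, max(params.duration_s - ARTIFACT_DURATION_S, 0.0)))
        end = start + ARTIFACT_DURATION_S
        i0, i1 = int(start * fs), min(int(end * fs), n)
        tt = t[i0:i1] - start
        signal[i0:i1] += ARTIFACT_GAIN * ptp * np.sin(np.pi * tt / ARTIFACT_DURATION_S)
        artifact_windows.append((start, end))

    # co-recorded invasive ICP channel (mmHg)
    pulse_zero_mean = clean - clean.mean()
    icp = (
        params.micp_mmhg
        + ICP_PULSE_AMP_MMHG * pulse_zero_mean / ptp
        + rng.normal(0.0, ICP_NOISE_SD_MMHG, n)
    )

    rec = RawRecording(samples=signal, fs_hz=fs, icp_samples=icp)
    gt = GroundTruth(
        onsets=np.asarray(onsets),
        true_p2p1=achieved_morphology(params.shape).p2p1,
        true_micp=params.micp_mmhg,
        artifact_windows=artifact_windows,
    )
    return rec, gt


# --------------------------------------------------------------------------
# binormal score calibration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BinormalParams:
    """Normal score distributions for hypertensive (pos) and normal (neg) patients."""

    mu_pos: float
    sd_pos: float
    mu_neg: float
    sd_neg: float

    def __post_init__(self) -> None:
        if self.sd_pos <= 0 or self.sd_neg <= 0:
            raise InvalidParameterError("standard deviations must be > 0")
        if not self.mu_pos > self.mu_neg:
            raise InvalidParameterError("mu_pos must exceed mu_neg")

    @property
    def auc(self) -> float:
        return float(
            norm.cdf((self.mu_pos - self.mu_neg) / math.hypot(self.sd_pos, self.sd_neg))
        )


def calibrate_binormal(
    target_auc: float = 0.88,
    target_sens: float = 0.85,
    target_spec: float = 0.77,
    cutoff: float = 1.2,
    sd_neg: float = 0.15,
) -> BinormalParams:
    """Binormal parameters hitting an AUROC and an operating point exactly.

    Solves the three equations

        P(X_pos > cutoff) = sens,   P(X_neg <= cutoff) = spec,
        Phi((mu_pos - mu_neg) / sqrt(sd_pos^2 + sd_neg^2)) = auc

    for (mu_pos, sd_pos, mu_neg) with ``sd_neg`` held fixed to make the
    3-equation / 4-unknown system determinate.  The default sd_neg = 0.15
    keeps negative-class ratios in a physiologic band around the 1.2 cutoff.
    """
    if not 0.5 < target_auc < 1:
        raise CalibrationInfeasibleError(
            f"target_auc must lie in (0.5, 1), got {target_auc}"
        )
    for name, v in (("target_sens", target_sens), ("target_spec", target_spec)):
        if not 0 < v < 1:
            raise CalibrationInfeasibleError(f"{name} must lie in (0, 1), got {v}")
    if not math.isfinite(cutoff):
        raise CalibrationInfeasibleError("cutoff must be finite")
    if sd_neg <= 0:
        raise CalibrationInfeasibleError("sd_neg must be > 0")

    z_sens = norm.ppf(target_sens)
    z_spec = norm.ppf(target_spec)
    z_auc = norm.ppf(target_auc)
    mu_neg = cutoff - sd_neg * z_spec

    # remaining equation in sd_pos after substituting mu_pos = cutoff + sd_pos*z_sens
    def f(s: float) -> float:
        return (cutoff + s * z_sens - mu_neg) / math.hypot(s, sd_neg) - z_auc

    grid = np.logspace(-4, 2, 400)
    vals = np.array([f(s) for s in grid])
    sign_change = np.flatnonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))
    if len(sign_change) == 0:
        raise CalibrationInfeasibleError(
            "no positive sd_pos satisfies the AUROC/operating-point targets"
        )
    roots = [
        float(optimize.brentq(f, grid[k], grid[k + 1], xtol=1e-14, rtol=1e-15))
        for k in sign_change
    ]
    # the system can admit two roots; prefer a positive class at least as
    # heterogeneous as the negative one (the physiologic case), and among
    # those the solution closest to sd_neg
    preferred = [s for s in roots if s >= sd_neg - 1e-12] or roots
    sd_pos = min(preferred, key=lambda s: abs(s - sd_neg))
    mu_pos = cutoff + sd_pos * z_sens
    params = BinormalParams(mu_pos=mu_pos, sd_pos=sd_pos, mu_neg=mu_neg, sd_neg=sd_neg)

    resid = max(
        abs(norm.sf((cutoff - mu_pos) / sd_pos) - target_sens),
        abs(norm.cdf((cutoff - mu_neg) / sd_neg) - target_spec),
        abs(params.auc - target_auc),
    )
    if resid > 1e-8:
        raise CalibrationInfeasibleError(
            f"calibration residual {resid:.3g} exceeds 1e-8"
        )
    return params


def draw_binormal_scores(
    params: BinormalParams,
    n: int,
    prevalence: float = 0.18,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` patient scores and binary hypertension labels."""
    if not 0 < prevalence < 1:
        raise InvalidParameterError("prevalence must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    labels = (rng.random(n) < prevalence).astype(int)
    pos = rng.normal(params.mu_pos, params.sd_pos, n)
    neg = rng.normal(params.mu_neg, params.sd_neg, n)
    scores = np.where(labels == 1, pos, neg)
    return scores, labels


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSimParams:
    """Cohort generator calibrated to the study population summaries.

    Session mean ICP is log-normal (right-skewed, as the cohort quartiles
    14 (11-19) mmHg suggest), fitted by least squares to the (median, Q1, Q3)
    targets.  Session P2/P1 follows a linear link
    ``intercept + slope * mICP + e`` with Gaussian residual; when
    ``link_noise_sd`` is None it is derived from the correlation identity
    r = b*sigma / sqrt(b^2 sigma^2 + sigma_e^2) so the untruncated mICP-P2/P1
    correlation equals ``target_r`` (default 0.49).  Ratios are truncated to a
    physiologic band.  Outcome groups (SB/MV/ED) are drawn with the observed
    cohort frequencies.
    """

    n_patients: int = 72
    prevalence_iht: float = 0.18
    micp_median: float = 14.0
    micp_q1: float = 11.0
    micp_q3: float = 19.0
    link_slope: float = 0.02
    link_intercept: float = 0.82
    link_noise_sd: float | None = None  # None -> derived from target_r
    target_r: float = 0.49
    ratio_bounds: tuple[float, float] = (0.4, 2.2)
    group_probs: tuple[float, float, float] = (15 / 72, 47 / 72, 10 / 72)  # SB, MV, ED
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise InvalidParameterError("n_patients must be >= 1")
        if not 0 < self.prevalence_iht < 1:
            raise InvalidParameterError("prevalence_iht must lie in (0, 1)")
        if not self.micp_q1 < self.micp_median < self.micp_q3:
            raise InvalidParameterError(
                "need micp_q1 < micp_median < micp_q3, got "
                f"({self.micp_q1}, {self.micp_median}, {self.micp_q3})"
            )
        if self.link_noise_sd is not None and self.link_noise_sd < 0:
            raise InvalidParameterError("link_noise_sd must be >= 0")
        if not 0 < self.target_r < 1:
            raise InvalidParameterError("target_r must lie in (0, 1)")
        if not self.ratio_bounds[0] < self.ratio_bounds[1]:
            raise InvalidParameterError("ratio_bounds must be ordered")
        if abs(sum(self.group_probs) - 1.0) > 1e-9:
            raise InvalidParameterError("group_probs must sum to 1")


def fit_lognormal_quartiles(
    median: float, q1: float, q3: float
) -> tuple[float, float]:
    """Least-squares log-normal (mu, sigma) matching a (median, Q1, Q3) triple.

    The three quantile equations are linear in (mu, sigma):
    mu = ln(median); mu -+ z75*sigma = ln(Q1)/ln(Q3) with z75 = Phi^-1(0.75).
    The closed-form least-squares solution averages the three mu estimates and
    takes sigma from the log-IQR.
    """
    if not q1 < median < q3:
        raise InvalidParameterError("need q1 < median < q3")
    if q1 <= 0:
        raise InvalidParameterError("log-normal quantiles must be positive")
    z75 = norm.ppf(0.75)
    sigma = (math.log(q3) - math.log(q1)) / (2 * z75)
    mu = (math.log(q1) + math.log(median) + math.log(q3)) / 3.0
    return mu, sigma


def lognormal_sd(mu: float, sigma: float) -> float:
    """Standard deviation of a log-normal(mu, sigma) variate."""
    return math.sqrt(math.exp(sigma**2) - 1.0) * math.exp(mu + sigma**2 / 2.0)


def derive_link_noise_sd(
    slope: float, sigma_micp: float, target_r: float
) -> float:
    """Residual SD making corr(mICP, intercept + slope*mICP + e) = target_r.

    From r = b*sigma / sqrt(b^2 sigma^2 + sigma_e^2):
    sigma_e = b*sigma * sqrt(1/r^2 - 1).
    """
    if not 0 < target_r < 1:
        raise InvalidParameterError("target_r must lie in (0, 1)")
    return abs(slope) * sigma_micp * math.sqrt(1.0 / target_r**2 - 1.0)


GROUP_LABELS = ("SB", "MV", "ED")

# covariate frequencies mirroring the study population (used only for
# table-building and subgroup demonstrations; no index depends on them)
_PATHOLOGY = ("TBI", "SAH", "ischemic_stroke", "hemorrhagic_stroke", "neoplasm")
_PATHOLOGY_P = (49 / 72, 12 / 72, 7 / 72, 3 / 72, 1 / 72)
_NEUROSURGERY = ("none", "craniotomy", "craniectomy")
_NEUROSURGERY_P = (17 / 72, 32 / 72, 23 / 72)
_MALE_FRAC = 47 / 72
_AGE_MEAN, _AGE_SD = 39.0, 21.0


def simulate_cohort(
    params: CohortSimParams = CohortSimParams(),
) -> tuple[pd.DataFrame, dict]:
    """Per-patient cohort table (id, group, micp, p2p1, bci, iht, covariates).

    Returns the table and a ground-truth dict with the fitted log-normal
    parameters, the residual SD actually used, and the untruncated correlation
    target.
    """
    rng = np.random.default_rng(params.seed)
    mu, sigma = fit_lognormal_quartiles(
        params.micp_median, params.micp_q1, params.micp_q3
    )
    sigma_micp = lognormal_sd(mu, sigma)
    sigma_e = (
        params.link_noise_sd
        if params.link_noise_sd is not None
        else derive_link_noise_sd(params.link_slope, sigma_micp, params.target_r)
    )

    n = params.n_patients
    micp = rng.lognormal(mu, sigma, n)
    p2p1_raw = (
        params.link_intercept
        + params.link_slope * micp
        + (rng.normal(0.0, sigma_e, n) if sigma_e > 0 else np.zeros(n))
    )
    p2p1 = np.clip(p2p1_raw, *params.ratio_bounds)

    group = rng.choice(GROUP_LABELS, size=n, p=params.group_probs)
    age = np.clip(rng.normal(_AGE_MEAN, _AGE_SD, n), 16, 95).round(0)
    sex = np.where(rng.random(n) < _MALE_FRAC, "M", "F")
    pathology = rng.choice(_PATHOLOGY, size=n, p=_PATHOLOGY_P)
    neurosurgery = rng.choice(_NEUROSURGERY, size=n, p=_NEUROSURGERY_P)

    df = pd.DataFrame(
        {
            "id": [f"P{i:04d}" for i in range(n)],
            "group": group,
            "micp": micp,
            "p2p1": p2p1,
            "bci": micp * p2p1,
            "iht": micp > 20.0,
            "p2p1_untruncated": p2p1_raw,
            "age": age,
            "sex": sex,
            "pathology": pathology,
            "neurosurgery": neurosurgery,
        }
    )
    info = {
        "lognormal_mu": mu,
        "lognormal_sigma": sigma,
        "sigma_micp": sigma_micp,
        "link_noise_sd": sigma_e,
        "target_r": params.target_r,
        "nominal_prevalence_iht": params.prevalence_iht,
    }
    return df, info


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------


def preset_session(name: str, seed: int | None = None, **overrides) -> SessionSimParams:
    """Named study conditions: preserved vs exhausted intracranial compliance.

    ``good-compliance`` uses a dominant percussion wave (P2/P1 ~ 0.9, mean ICP
    12 mmHg); ``poor-compliance`` a dominant tidal wave (P2/P1 ~ 1.3, mean ICP
    24 mmHg).
    """
    if name == "good-compliance":
        base = SessionSimParams(
            shape=shape_with_ratio(0.9), micp_mmhg=12.0, seed=seed, **overrides
        )
    elif name == "poor-compliance":
        base = SessionSimParams(
            shape=shape_with_ratio(1.3), micp_mmhg=24.0, seed=seed, **overrides
        )
    else:
        raise InvalidParameterError(
            f"unknown preset {name!r}; use 'good-compliance' or 'poor-compliance'"
        )
    return base
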