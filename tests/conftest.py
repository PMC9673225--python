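import numpy as np
import pytest

from icpw import simulate as sim
from icpw.analysis_run import analyze_recording


def dense_grid_morphology(shape, n_grid=100_000, p1_win=(0.05, 0.28), p2_win=(0.28, 0.60)):
    """Test-local oracle: achieved P1/P2 of the analytic three-Gaussian sum.

    Evaluates the sum on a dense grid and reads the highest local maximum in
    each latency window (falling back to the window maximum), independently of
    the package's own peak-location code.
    """
    u = np.arange(n_grid) / n_grid
    y = shape.evaluate(u)
    base = y[0]

    def peak(lo, hi):
        idx = np.flatnonzero((u > lo) & (u <= hi))
        seg = y[idx]
        interior = np.flatnonzero((seg[1:-1] > seg[:-2]) & (seg[1:-1] >= seg[2:])) + 1
        if len(interior):
            k = interior[np.argmax(seg[interior])]
        else:
            k = int(np.argmax(seg))
        return u[idx[k]], y[idx[k]]

    l1, v1 = peak(*p1_win)
    l2, v2 = peak(*p2_win)
    return {"p1_lat": l1, "p2_lat": l2, "p1_amp": v1 - base, "p2_amp": v2 - base,
            "p2p1": (v2 - base) / (v1 - base)}


@pytest.fixture(scope="session")
def default_session():
    """One default 10-minute simulated session, analyzed once and shared."""
    rec, gt = sim.simulate_recording(sim.SessionSimParams(seed=20_260_101 % 2**31))
    ana = analyze_recording(rec)
    return rec, gt, ana


@pytest.fixture(scope="session")
def clean_session_60bpm():
    params = sim.SessionSimParams(
        heart_rate_bpm=60.0,
        hr_jitter_frac=0.0,
        drift_amp=0.0,
        noise_sd=0.0,
        artifact_rate_per_min=0.0,
        duration_s=30.0,
        seed=0,
    )
    return sim.simulate_recording(params)
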