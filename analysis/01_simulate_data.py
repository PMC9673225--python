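#!/usr/bin/env python
"""Generate the synthetic study data: two monitoring sessions and a cohort.

Writes the 72-patient cohort table (the study's sample size) to results/ and
the two full 10-minute waveform recordings — one preserved-compliance, one
exhausted-compliance session — to scratch/data/ (they are several MB each).
"""

import json
from pathlib import Path

from icpw import simulate as sim
from icpw.cohort import write_recording_csv

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "data"
SEED = 11

def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)

    cohort, info = sim.simulate_cohort(sim.CohortSimParams(n_patients=72, seed=SEED))
    cohort.to_csv(RESULTS / "cohort.csv", index=False, float_format="%.6g")
    (RESULTS / "cohort_info.json").write_text(json.dumps(info, indent=2))
    print(f"cohort: 72 patients, {int(cohort['iht'].sum())} with mICP > 20 mmHg, "
          f"groups {cohort['group'].value_counts().to_dict()}")

    for i, preset in enumerate(("good-compliance", "poor-compliance")):
        params = sim.preset_session(preset, seed=SEED + i)
        rec, gt = sim.simulate_recording(params)
        write_recording_csv(SCRATCH / f"recording_{preset}.csv",
                            rec.samples, rec.fs_hz, rec.icp_samples)
        (SCRATCH / f"ground_truth_{preset}.json").write_text(json.dumps(
            {"true_p2p1": gt.true_p2p1, "true_micp": gt.true_micp,
             "n_beats": len(gt.onsets),
             "artifact_windows": gt.artifact_windows}, indent=2))
        print(f"{preset}: {len(gt.onsets)} beats, true P2/P1 = {gt.true_p2p1:.3f}, "
              f"true mICP = {gt.true_micp:.1f} mmHg")


if __name__ == "__main__":
    main()
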