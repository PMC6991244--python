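"""Estimate the label-noise ceiling on achievable balanced accuracy.

Takes the cohort's MADRS baseline/week-8 pairs as ground truth, adds
Gaussian measurement noise of increasing SD to both visits, re-derives the
responder labels from the noisy scores, and scores the oracle that always
predicts the true label.  Writes the sigma curve to
results/noise_ceiling.csv.  The ceiling at plausible rating noise (a few
MADRS points) is the honest upper bound to compare any classifier's
cross-validated accuracy against.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import RESULTS, SEED, ensure_dirs

from restpredict.clinical import read_clinical_csv
from restpredict.noise_bound import ceiling_curve

SIGMAS = [0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0]


def main() -> None:
    ensure_dirs()
    records = [r for r in read_clinical_csv(RESULTS / "clinical.csv")
               if r.madrs_week8 is not None and r.madrs_baseline > 0]
    baseline = np.array([r.madrs_baseline for r in records])
    week8 = np.array([r.madrs_week8 for r in records])

    curve = ceiling_curve(baseline, week8, SIGMAS, n_replicates=5000, seed=SEED)
    table = pd.DataFrame(
        {
            "sigma_madrs_points": [c.sigma for c in curve],
            "ceiling_pct": [c.ceiling_pct for c in curve],
            "ci_low_pct": [c.ci_low_pct for c in curve],
            "ci_high_pct": [c.ci_high_pct for c in curve],
        }
    )
    table.to_csv(RESULTS / "noise_ceiling.csv", index=False, float_format="%.2f")
    print(table.round(1).to_string(index=False))
    print(f"\nwith ~3 points of rating noise the ceiling is "
          f"{table.loc[table.sigma_madrs_points == 3.0, 'ceiling_pct'].iloc[0]:.1f}% — "
          "no classifier evaluated against these labels can honestly beat that.")


if __name__ == "__main__":
    main()
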