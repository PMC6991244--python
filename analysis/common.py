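"""Shared configuration for the analysis scripts.

The study cohort is emulated at desk scale: 40 subjects over four sites with
the same qualitative structure as the full 122-subject population
(imbalanced sites, ~45% responders, a few subjects missing the week-2
recording), an 8-electrode 10-20 montage, and 40-second recordings.  Known
group effects are injected so that each stage has signal to find: a
complexity (entropy) difference over frontocentral channels at both
timepoints, a posterior high-alpha power difference at both timepoints, and
a frontal middle-beta difference that only emerges at week 2 (so the early
change source has ground truth of its own).
"""

from pathlib import Path

import restpredict.pipeline as pl
from restpredict.synthdata import CohortConfig, EffectSpec

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch" / "analysis"

SEED = 2024

MONTAGE = ("F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2")

COHORT = CohortConfig(
    n_subjects=40,
    site_sizes=(18, 12, 6, 4),
    site_names=("UBC", "TGH", "QNS", "CAM"),
    responder_fraction=0.45,
    week2_missing_fraction=2 / 40,
    duration=40.0,
    montage=MONTAGE,
    effects=(
        EffectSpec("mse", ("F3", "F4", "C3", "C4"), 1.2),
        EffectSpec("band_power", ("P3", "P4", "O1", "O2"), 1.0, band="high_alpha"),
        EffectSpec("band_power", ("F3", "F4"), 0.8, band="middle_beta",
                   timepoints=("week2",)),
    ),
    seed=SEED,
)

PREPROCESS = pl.PreprocessConfig(min_epochs=12)
FEATURES = pl.FeatureConfig(microstate_restarts=5, n_sources=120)
EVALUATION = pl.EvalConfig(ranking_min_per_class=8)


def ensure_dirs() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
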