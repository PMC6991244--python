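"""Monte Carlo ceiling on prediction accuracy induced by outcome-label noise.

Responder labels are derived from a clinician-rated score that is itself
noisy: repeated assessment of the same patient yields somewhat different
values.  An ideal predictor that always outputs the *true* (noise-free)
label therefore cannot agree perfectly with labels derived from noisy
measurements, which caps the accuracy any real model can honestly attain.

The estimator treats the supplied baseline/week-8 score pairs as the truth,
adds independent Gaussian measurement noise (SD sigma, in scale points) to
the measured scores, derives observed labels from the noisy scores via the
>= 50% decrease rule, and scores the oracle (true labels) against the
observed labels with balanced accuracy.  The ceiling is the mean over
replicates, with a percentile confidence interval.  All randomness comes
from the config seed, so a grid of sigmas evaluated with the same seed
shares its random draws (common random numbers) and the estimated ceiling
is monotone non-increasing in sigma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class NoiseBoundConfig:
    """Inputs of the ceiling estimate.

    ``noise_on`` selects whether measurement noise perturbs both visits
    (default) or only the week-8 score.
    """

    sigma: float
    n_replicates: int = 1000
    seed: int = 0
    noise_on: str = "both"  # "both" | "week8"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise SD sigma must be >= 0")
        if self.n_replicates < 100:
            raise ValueError("need at least 100 Monte Carlo replicates")
        if self.noise_on not in ("both", "week8"):
            raise ValueError("noise_on must be 'both' or 'week8'")


@dataclass
class CeilingEstimate:
    ceiling_pct: float
    ci_low_pct: float
    ci_high_pct: float
    sigma: float
    n_replicates: int


def _observed_responder(baseline: np.ndarray, week8: np.ndarray) -> np.ndarray:
    """>= 50% decrease rule, written to stay defined for noisy scores <= 0."""
    return week8 <= 0.5 * baseline


def estimate_ceiling(
    baseline: np.ndarray, week8: np.ndarray, config: NoiseBoundConfig
) -> CeilingEstimate:
    """Label-noise ceiling (percent balanced accuracy) for a score cohort.

    Per replicate, noisy measured scores define the observed labels; the
    oracle predicting the noise-free label is scored against them.
    Replicates in which the observed labels are all one class contribute the
    defined rate only through the pooled mean (they are skipped, which can
    only happen at extreme sigma on tiny cohorts).
    """
    baseline = np.asarray(baseline, dtype=float)
    week8 = np.asarray(week8, dtype=float)
    if baseline.shape != week8.shape or baseline.ndim != 1:
        raise ValueError("baseline and week8 must be matching 1-D score vectors")
    if np.any(baseline <= 0):
        raise ValueError("baseline scores must be > 0")

    true_resp = _observed_responder(baseline, week8)
    rng = np.random.default_rng(config.seed)
    n = baseline.size
    # Draws are fixed by (seed, n_replicates, n); sigma only scales them, so
    # a sigma grid under one seed uses common random numbers.
    z_b = rng.standard_normal((config.n_replicates, n))
    z_w = rng.standard_normal((config.n_replicates, n))

    vals = []
    for r in range(config.n_replicates):
        noisy_w = week8 + config.sigma * z_w[r]
        noisy_b = baseline + (config.sigma * z_b[r] if config.noise_on == "both" else 0.0)
        obs = _observed_responder(noisy_b, noisy_w)
        n_pos, n_neg = int(obs.sum()), int((~obs).sum())
        if n_pos == 0 or n_neg == 0:
            continue
        sens = np.sum(true_resp & obs) / n_pos
        spec = np.sum(~true_resp & ~obs) / n_neg
        vals.append(50.0 * (sens + spec))
    if not vals:
        raise RuntimeError("every replicate produced a single observed class")
    vals_arr = np.asarray(vals)
    lo, hi = np.percentile(vals_arr, [2.5, 97.5])
    return CeilingEstimate(
        ceiling_pct=float(vals_arr.mean()),
        ci_low_pct=float(lo),
        ci_high_pct=float(hi),
        sigma=config.sigma,
        n_replicates=config.n_replicates,
    )


def ceiling_curve(
    baseline: np.ndarray,
    week8: np.ndarray,
    sigmas: list[float],
    n_replicates: int = 1000,
    seed: int = 0,
    noise_on: str = "both",
) -> list[CeilingEstimate]:
    """Ceiling over a sigma grid with common random numbers (same seed)."""
    return [
        estimate_ceiling(
            baseline, week8,
            NoiseBoundConfig(sigma=s, n_replicates=n_replicates, seed=seed,
                             noise_on=noise_on),
        )
        for s in sigmas
    ]
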