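"""Multiscale entropy (MSE) features.

Sample entropy quantifies signal irregularity as the negative log of the
conditional probability that two subsequences matching for ``m`` points
(within a tolerance ``r``, Chebyshev distance, self-matches excluded) also
match at ``m + 1`` points.  Multiscale entropy evaluates sample entropy on
successively coarse-grained (non-overlapping block-averaged) copies of the
signal, indexing complexity across timescales; a 70-scale grid is used by
default.  The tolerance is fixed in *absolute* units from the scale-1 SD and
held constant across scales, following the original multiscale-entropy
convention, so that entropy changes across scales reflect the coarse-graining
and not a re-normalised tolerance.

Hemispheric complexity asymmetry is the per-scale normalised left/right
difference for homologous electrode pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit


@dataclass(frozen=True)
class MSEConfig:
    """Parameters of the multiscale entropy extractor.

    Attributes
    ----------
    m : template length (points); 2 is the standard choice for physiological
        series.
    r : tolerance as a fraction of the scale-1 signal SD.
    n_scales : number of coarse-graining scales (1..n_scales).
    min_coarse_length : minimum coarse-grained length for a scale's entropy
        to be considered valid; shorter scales yield NaN.
    """

    m: int = 2
    r: float = 0.15
    n_scales: int = 70
    min_coarse_length: int = 100

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("template length m must be >= 1")
        if not (0.0 < self.r < 1.0):
            raise ValueError("tolerance fraction r must be in (0, 1)")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")


def coarse_grain(x: np.ndarray, tau: int) -> np.ndarray:
    """Non-overlapping block average of ``x`` with block length ``tau``.

    Output element ``k`` is the mean of ``x[k*tau : (k+1)*tau]``; the trailing
    remainder is discarded, so the output has ``len(x) // tau`` elements.
    """
    if tau < 1:
        raise ValueError(f"coarse-graining scale must be >= 1, got {tau}")
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[0] // tau
    if n == 0:
        raise ValueError(f"signal of length {x.shape[0]} too short for scale {tau}")
    return x[: n * tau].reshape(n, tau).mean(axis=1)


@njit(cache=True)
def _template_match_counts(x: np.ndarray, m: int, r: float):  # pragma: no cover
    """Counts of template pairs matching at length m (B) and m+1 (A).

    Pairs (i, j), i < j, both over the first n-m template start points so that
    every counted m-template has an (m+1)-extension; Chebyshev distance.
    """
    n = x.shape[0]
    a = 0
    b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            d = 0.0
            for k in range(m):
                t = abs(x[i + k] - x[j + k])
                if t > d:
                    d = t
            if d <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


def sample_entropy(x: np.ndarray, m: int = 2, r_absolute: float | None = None) -> float:
    """Sample entropy of a 1-D sequence with an *absolute* tolerance.

    Returns ``-ln(A/B)`` where B counts template pairs of length ``m`` within
    ``r_absolute`` (Chebyshev distance, self-matches excluded) and A counts
    the same pairs still matching at length ``m + 1``.  Returns ``nan`` when
    either count is zero (the estimate is undefined; never silently +/-inf).
    """
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("sample_entropy expects a 1-D sequence")
    if x.shape[0] < m + 2:
        raise ValueError(f"need at least m + 2 = {m + 2} samples, got {x.shape[0]}")
    if r_absolute is None or not np.isfinite(r_absolute) or r_absolute <= 0:
        raise ValueError("r_absolute must be a positive finite tolerance")
    a, b = _template_match_counts(x, m, r_absolute)
    if a == 0 or b == 0:
        return float("nan")
    return float(-np.log(a / b))


def mse_curve(signal: np.ndarray, config: MSEConfig = MSEConfig()) -> np.ndarray:
    """Sample entropy at every coarse-graining scale 1..n_scales.

    ``signal`` is the concatenated artifact-free record of one channel.  The
    tolerance is ``config.r`` times the SD of the *original* (scale-1) signal
    and is held fixed across scales.  Scales whose coarse-grained length falls
    below ``min_coarse_length`` (or below ``m + 2``) are NaN.  Raises if every
    scale is invalid.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1:
        raise ValueError("mse_curve expects a 1-D channel signal")
    sd = float(np.std(signal))
    out = np.full(config.n_scales, np.nan)
    if sd == 0.0:
        # Entropy of a constant signal is 0 at every defined scale.
        pass
    else:
        r_abs = config.r * sd
        for tau in range(1, config.n_scales + 1):
            n_coarse = signal.shape[0] // tau
            if n_coarse < max(config.min_coarse_length, config.m + 2):
                continue
            out[tau - 1] = sample_entropy(coarse_grain(signal, tau), config.m, r_abs)
    if sd == 0.0:
        for tau in range(1, config.n_scales + 1):
            n_coarse = signal.shape[0] // tau
            if n_coarse >= max(config.min_coarse_length, config.m + 2):
                out[tau - 1] = 0.0
    if np.all(np.isnan(out)):
        raise ValueError(
            "all multiscale-entropy scales are invalid for this signal length"
        )
    return out


def entropy_asymmetry(left_curve: np.ndarray, right_curve: np.ndarray) -> np.ndarray:
    """Per-scale normalised left/right difference ``(L - R) / (L + R)``.

    NaN wherever either side is missing or the denominator is zero.
    """
    left = np.asarray(left_curve, dtype=np.float64)
    right = np.asarray(right_curve, dtype=np.float64)
    if left.shape != right.shape:
        raise ValueError("asymmetry requires curves on the same scale grid")
    denom = left + right
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (left - right) / denom
    out[~np.isfinite(out)] = np.nan
    return out
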