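"""Stability-voting feature ranking.

Each feature receives an integer score of 0 to 100: at each of 100
iterations, 80% of the subjects are drawn without replacement (stratified by
outcome class to preserve the class ratio), an unpaired two-tailed Welch
t-test compares responders with nonresponders on the subsample, and the
feature earns one vote if p < alpha.  Features are then selected by a vote
threshold T (inclusive: votes >= T).  Because each iteration sees a
different subsample, the score measures how *robustly* a feature separates
the classes rather than the strength of a single test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_ITERATIONS = 100
DEFAULT_FRACTION = 0.8
DEFAULT_ALPHA = 0.05
#: minimum non-missing values per class for a feature to be rankable
MIN_PER_CLASS = 10


class EmptySelectionError(ValueError):
    pass


def welch_ttest_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-tailed unequal-variance (Welch) t-test p-values, column-wise.

    NaN entries are omitted per column.  Columns with fewer than two
    non-missing values in either group, or zero variance in both, get NaN.
    Vectorised replacement for per-column ``scipy.stats.ttest_ind(...,
    equal_var=False, nan_policy="omit")``, which is orders of magnitude
    slower on wide matrices.
    """
    import warnings

    n1 = (~np.isnan(a)).sum(axis=0).astype(float)
    n2 = (~np.isnan(b)).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1, m2 = np.nanmean(a, axis=0), np.nanmean(b, axis=0)
        v1 = np.nanvar(a, axis=0, ddof=1)
        v2 = np.nanvar(b, axis=0, ddof=1)
        se2 = v1 / n1 + v2 / n2
        t = (m1 - m2) / np.sqrt(se2)
        # Welch-Satterthwaite degrees of freedom
        df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p[(n1 < 2) | (n2 < 2)] = np.nan
    return p


@dataclass
class VoteTable:
    """Per-feature vote counts plus the ranking configuration that made them."""

    votes: pd.Series  # int, indexed by feature key
    n_iterations: int
    fraction: float
    alpha: float
    seed: int

    def __post_init__(self) -> None:
        if ((self.votes < 0) | (self.votes > self.n_iterations)).any():
            raise ValueError("votes must lie in [0, n_iterations]")

    def to_csv(self, path) -> None:
        out = self.votes.rename("votes").to_frame()
        out.index.name = "feature"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path, n_iterations=DEFAULT_ITERATIONS, fraction=DEFAULT_FRACTION,
                 alpha=DEFAULT_ALPHA, seed=0) -> "VoteTable":
        votes = pd.read_csv(path, index_col="feature")["votes"]
        return cls(votes=votes, n_iterations=n_iterations, fraction=fraction,
                   alpha=alpha, seed=seed)


def rank_features(
    values: pd.DataFrame,
    labels: pd.Series,
    n_iterations: int = DEFAULT_ITERATIONS,
    fraction: float = DEFAULT_FRACTION,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
    min_per_class: int = MIN_PER_CLASS,
) -> VoteTable:
    """Vote-count every feature by repeated subsample t-tests.

    ``values`` is subjects x features (NaN = missing); ``labels`` holds
    "responder"/"nonresponder" aligned with the rows.  Features without at
    least :data:`MIN_PER_CLASS` non-missing values in each class are dropped
    with a log entry.  Deterministic given the seed.
    """
    labels = labels.loc[values.index]
    classes = labels.unique()
    if set(classes) != {"responder", "nonresponder"}:
        raise ValueError(f"both outcome classes must be present, got {sorted(classes)}")

    x = values.to_numpy(dtype=float)
    is_resp = (labels == "responder").to_numpy()
    idx_resp = np.flatnonzero(is_resp)
    idx_non = np.flatnonzero(~is_resp)

    ok = (
        (~np.isnan(x[idx_resp])).sum(axis=0) >= min_per_class
    ) & ((~np.isnan(x[idx_non])).sum(axis=0) >= min_per_class)
    if not ok.all():
        logger.info(
            "dropping %d features with < %d non-missing values per class",
            int((~ok).sum()), min_per_class,
        )
    if not ok.any():
        raise ValueError("no rankable features")
    kept_cols = values.columns[ok]
    x = x[:, ok]

    n_resp_draw = int(round(fraction * idx_resp.size))
    n_non_draw = int(round(fraction * idx_non.size))
    if n_resp_draw < 2 or n_non_draw < 2:
        raise ValueError("subsample too small for a two-sample t-test")

    rng = np.random.default_rng(seed)
    votes = np.zeros(x.shape[1], dtype=int)
    for _ in range(n_iterations):
        sub_r = rng.choice(idx_resp, size=n_resp_draw, replace=False)
        sub_n = rng.choice(idx_non, size=n_non_draw, replace=False)
        p = welch_ttest_pvalues(x[sub_r], x[sub_n])
        votes += (p < alpha) & np.isfinite(p)

    return VoteTable(
        votes=pd.Series(votes, index=kept_cols, name="votes"),
        n_iterations=n_iterations,
        fraction=fraction,
        alpha=alpha,
        seed=seed,
    )


def select_features(vote_table: VoteTable, threshold: float) -> list[str]:
    """Feature keys with votes >= threshold (inclusive).

    Raises :class:`EmptySelectionError` (suggesting a lower threshold) when
    nothing passes.
    """
    if not (0 <= threshold <= vote_table.n_iterations):
        raise ValueError(
            f"threshold must lie in [0, {vote_table.n_iterations}], got {threshold}"
        )
    selected = vote_table.votes.index[vote_table.votes >= threshold].tolist()
    if not selected:
        raise EmptySelectionError(
            f"no features reach {threshold} votes "
            f"(max is {int(vote_table.votes.max())}); lower the threshold"
        )
    return selected
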