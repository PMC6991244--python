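"""RBF-SVM classification with nested cross-validation and leave-one-site-out.

Responder status is the positive class.  Performance is summarised by
sensitivity, specificity, and balanced accuracy (their mean), which is
robust to the ~45/55 class imbalance.  Hyperparameters (C, gamma) are chosen
by an inner stratified grid search maximising balanced accuracy; feature
ranking, selection, and z-scoring are all refit inside each training
partition so that held-out subjects never influence any fitted statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score, pairwise
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .ranking import (
    DEFAULT_ALPHA,
    DEFAULT_FRACTION,
    DEFAULT_ITERATIONS,
    VoteTable,
    rank_features,
    select_features,
)

logger = logging.getLogger(__name__)

POSITIVE = "responder"
NEGATIVE = "nonresponder"

DEFAULT_C_GRID = tuple(float(2.0**k) for k in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(float(2.0**k) for k in range(-15, 4, 2))
DEFAULT_VOTE_THRESHOLDS = (50, 60, 70, 80, 90)


@dataclass(frozen=True)
class ModelSpec:
    """RBF-SVM configuration: search grids, inner folds, vote threshold."""

    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    inner_folds: int = 5
    vote_threshold: float = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.C_grid or not self.gamma_grid:
            raise ValueError("hyperparameter grids must be non-empty")


@dataclass
class EvalReport:
    """Confusion counts and accuracy metrics per partition plus pooled.

    ``table`` has one row per partition (fold or held-out site) and a final
    ``pooled`` row; sensitivity/specificity/balanced accuracy are percentages
    recomputed from the counts.  Partitions whose test set lacks a class have
    the undefined rate (and balanced accuracy) marked NaN and flagged.
    """

    table: pd.DataFrame
    scheme: str

    @property
    def pooled(self) -> pd.Series:
        return self.table.loc["pooled"]

    @property
    def balanced_accuracy_pct(self) -> float:
        return float(self.table.loc["pooled", "balanced_accuracy"])

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="index", indent=2)


def balanced_accuracy(sensitivity: float, specificity: float) -> float:
    """Mean of sensitivity and specificity (percent in, percent out)."""
    if not (0.0 <= sensitivity <= 100.0 and 0.0 <= specificity <= 100.0):
        raise ValueError("sensitivity and specificity must be percentages in [0, 100]")
    return (sensitivity + specificity) / 2.0


def _metrics_row(tp: int, fp: int, tn: int, fn: int) -> dict:
    n_pos, n_neg = tp + fn, tn + fp
    sens = 100.0 * tp / n_pos if n_pos else np.nan
    spec = 100.0 * tn / n_neg if n_neg else np.nan
    bal = balanced_accuracy(sens, spec) if n_pos and n_neg else np.nan
    return {
        "n": n_pos + n_neg,
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sensitivity": sens, "specificity": spec, "balanced_accuracy": bal,
        "degenerate": not (n_pos and n_neg),
    }


def _finish_report(rows: dict[str, dict], scheme: str) -> EvalReport:
    pooled = _metrics_row(
        sum(r["tp"] for r in rows.values()),
        sum(r["fp"] for r in rows.values()),
        sum(r["tn"] for r in rows.values()),
        sum(r["fn"] for r in rows.values()),
    )
    table = pd.DataFrame({**rows, "pooled": pooled}).T
    return EvalReport(table=table, scheme=scheme)


@dataclass
class FittedModel:
    """Z-scored RBF SVM with hyperparameters chosen by inner stratified CV."""

    scaler: StandardScaler
    svc: SVC
    best_C: float
    best_gamma: float
    inner_score: float

    @property
    def best_params_(self) -> dict:
        return {"C": self.best_C, "gamma": self.best_gamma}

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.svc.predict(self.scaler.transform(x))


def _inner_grid_search(
    x: np.ndarray, y: np.ndarray, spec: ModelSpec
) -> tuple[float, float, float]:
    """Best (C, gamma, score) by stratified inner CV on balanced accuracy.

    Scaling is refit inside every inner fold; RBF kernels are precomputed per
    (fold, gamma) and shared across the C grid.  Ties break toward the first
    grid entry (smaller gamma, then smaller C), deterministically.
    """
    skf = StratifiedKFold(spec.inner_folds, shuffle=True, random_state=spec.seed)
    scores = np.zeros((len(spec.gamma_grid), len(spec.C_grid)))
    n_folds = 0
    for tr, te in skf.split(x, y):
        n_folds += 1
        scaler = StandardScaler().fit(x[tr])
        xtr, xte = scaler.transform(x[tr]), scaler.transform(x[te])
        for gi, gamma in enumerate(spec.gamma_grid):
            k_tr = pairwise.rbf_kernel(xtr, xtr, gamma=gamma)
            k_te = pairwise.rbf_kernel(xte, xtr, gamma=gamma)
            for ci, c in enumerate(spec.C_grid):
                svc = SVC(kernel="precomputed", C=c, class_weight="balanced")
                svc.fit(k_tr, y[tr])
                scores[gi, ci] += balanced_accuracy_score(y[te], svc.predict(k_te))
    scores /= n_folds
    gi, ci = np.unravel_index(np.argmax(scores), scores.shape)
    return spec.C_grid[ci], spec.gamma_grid[gi], float(scores[gi, ci])


def train_classifier(
    values: pd.DataFrame, labels: pd.Series, spec: ModelSpec = ModelSpec()
) -> FittedModel:
    """Fit a z-scored RBF SVM with inner stratified grid search.

    ``values`` must already be restricted to the selected features; the
    scaler is fitted on these training rows only.  Class-weighted hinge loss
    compensates for outcome imbalance.  Deterministic given the spec seed.
    """
    y = labels.loc[values.index]
    if y.nunique() < 2:
        raise ValueError("training set must contain both outcome classes")
    x = values.to_numpy(dtype=float)
    yb = (y == POSITIVE).to_numpy().astype(int)
    best_c, best_gamma, score = _inner_grid_search(x, yb, spec)
    scaler = StandardScaler().fit(x)
    svc = SVC(kernel="rbf", C=best_c, gamma=best_gamma, class_weight="balanced")
    svc.fit(scaler.transform(x), yb)
    return FittedModel(
        scaler=scaler, svc=svc, best_C=best_c, best_gamma=best_gamma, inner_score=score
    )


def _fit_predict_partition(
    values: pd.DataFrame,
    labels: pd.Series,
    train_idx: pd.Index,
    test_idx: pd.Index,
    spec: ModelSpec,
    nested_ranking: bool,
    vote_table: VoteTable | None,
    ranking_kwargs: dict,
) -> dict:
    """Rank/select/scale/train on the training split, score the test split."""
    if nested_ranking or vote_table is None:
        vote_table = rank_features(
            values.loc[train_idx], labels.loc[train_idx], **ranking_kwargs
        )
    selected = select_features(vote_table, spec.vote_threshold)

    train = values.loc[train_idx, selected]
    test = values.loc[test_idx, selected]
    # subjects missing any selected feature cannot be scored by the SVM
    train_ok = train.dropna()
    test_ok = test.dropna()
    n_drop = (len(train) - len(train_ok)) + (len(test) - len(test_ok))
    if n_drop:
        logger.info("dropped %d subjects with missing selected features", n_drop)

    model = train_classifier(train_ok, labels, spec)
    y_true = (labels.loc[test_ok.index] == POSITIVE).to_numpy().astype(int)
    y_pred = model.predict(test_ok.to_numpy())
    return _metrics_row(
        tp=int(np.sum((y_pred == 1) & (y_true == 1))),
        fp=int(np.sum((y_pred == 1) & (y_true == 0))),
        tn=int(np.sum((y_pred == 0) & (y_true == 0))),
        fn=int(np.sum((y_pred == 0) & (y_true == 1))),
    )


def cross_validate(
    values: pd.DataFrame,
    labels: pd.Series,
    spec: ModelSpec = ModelSpec(),
    k: int = 10,
    nested_ranking: bool = True,
    seed: int = 0,
    n_iterations: int = DEFAULT_ITERATIONS,
    fraction: float = DEFAULT_FRACTION,
    alpha: float = DEFAULT_ALPHA,
    min_per_class: int = 10,
) -> EvalReport:
    """Stratified k-fold cross-validation of the full selection + SVM chain.

    With ``nested_ranking`` (default) the vote table is recomputed inside
    each training partition, so feature selection never sees held-out
    subjects; the non-nested mode ranks once on all data (for comparison
    only — its estimate is optimistically biased).
    """
    labels = labels.loc[values.index]
    if len(values) < 2 * k:
        raise ValueError(f"need at least {2 * k} subjects for {k}-fold CV")
    ranking_kwargs = dict(
        n_iterations=n_iterations, fraction=fraction, alpha=alpha, seed=seed,
        min_per_class=min_per_class,
    )
    vote_table = None
    if not nested_ranking:
        vote_table = rank_features(values, labels, **ranking_kwargs)

    y = (labels == POSITIVE).to_numpy().astype(int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows: dict[str, dict] = {}
    for fold, (tr, te) in enumerate(skf.split(values.to_numpy(), y)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {fold}: training partition lacks a class")
        rows[f"fold_{fold}"] = _fit_predict_partition(
            values, labels, values.index[tr], values.index[te],
            spec, nested_ranking, vote_table, ranking_kwargs,
        )
    return _finish_report(rows, scheme=f"stratified {k}-fold")


def leave_one_site_out(
    values: pd.DataFrame,
    labels: pd.Series,
    sites: pd.Series,
    spec: ModelSpec = ModelSpec(),
    seed: int = 0,
    n_iterations: int = DEFAULT_ITERATIONS,
    fraction: float = DEFAULT_FRACTION,
    alpha: float = DEFAULT_ALPHA,
    min_per_class: int = 10,
) -> EvalReport:
    """Hold out each site in turn; train (ranking included) on the rest.

    Sites whose test set lacks a class get NaN for the undefined rate and a
    ``degenerate`` flag.  Raises on a single-site cohort.
    """
    labels = labels.loc[values.index]
    sites = sites.loc[values.index]
    site_names = sites.unique().tolist()
    if len(site_names) < 2:
        raise ValueError("leave-one-site-out requires at least 2 sites")
    ranking_kwargs = dict(
        n_iterations=n_iterations, fraction=fraction, alpha=alpha, seed=seed,
        min_per_class=min_per_class,
    )
    rows: dict[str, dict] = {}
    for site in site_names:
        test_idx = values.index[sites == site]
        train_idx = values.index[sites != site]
        rows[str(site)] = _fit_predict_partition(
            values, labels, train_idx, test_idx,
            spec, True, None, ranking_kwargs,
        )
    return _finish_report(rows, scheme="leave-one-site-out")


def threshold_source_grid(
    sources: dict[str, tuple[pd.DataFrame, pd.Series]],
    thresholds: tuple[float, ...] = DEFAULT_VOTE_THRESHOLDS,
    spec: ModelSpec = ModelSpec(),
    k: int = 10,
    seed: int = 0,
    **ranking_kwargs,
) -> pd.DataFrame:
    """Balanced accuracy (and feature count) per vote threshold x feature source.

    ``sources`` maps a feature-source name to its (values, labels).  Feature
    counts are from a ranking on all data (descriptive, matching how a final
    model would be built); accuracies are from nested cross-validation.
    Cells where no feature reaches the threshold are NaN.
    """
    from .ranking import EmptySelectionError

    records = []
    for name, (values, labels) in sources.items():
        full_votes = rank_features(values, labels, seed=seed, **ranking_kwargs)
        for thr in thresholds:
            row = {"source": name, "threshold": thr}
            try:
                row["n_features"] = len(select_features(full_votes, thr))
                rep = cross_validate(
                    values, labels,
                    spec=ModelSpec(
                        C_grid=spec.C_grid, gamma_grid=spec.gamma_grid,
                        inner_folds=spec.inner_folds, vote_threshold=thr,
                        seed=spec.seed,
                    ),
                    k=k, seed=seed, **ranking_kwargs,
                )
                row["balanced_accuracy"] = rep.balanced_accuracy_pct
            except EmptySelectionError:
                row["n_features"] = 0
                row["balanced_accuracy"] = np.nan
            records.append(row)
    return pd.DataFrame(records).set_index(["source", "threshold"])
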