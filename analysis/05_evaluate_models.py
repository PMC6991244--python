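"""Train and evaluate RBF-SVM classifiers across vote thresholds and sources.

Produces the threshold x feature-source grid of nested 10-fold balanced
accuracies with feature counts (results/accuracy_grid.csv) and the
leave-one-site-out per-site table at T=60 (results/loso.csv), mirroring how
a multicenter prediction study reports in-sample and cross-site performance.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import EVALUATION, RESULTS, SCRATCH, SEED, ensure_dirs

from restpredict.assembly import attach_clinical, build_source
from restpredict.clinical import labels_from_records, read_clinical_csv
from restpredict.model_eval import ModelSpec, leave_one_site_out, threshold_source_grid


def main() -> None:
    ensure_dirs()
    clinical = read_clinical_csv(RESULTS / "clinical.csv")
    labels = labels_from_records(clinical)
    sites = pd.Series({c.subject_id: c.site for c in clinical})
    feats = {
        tp: pd.read_csv(SCRATCH / f"features_{tp}.csv", index_col="subject_id")
        for tp in ("baseline", "week2")
    }

    rank_kwargs = dict(
        n_iterations=EVALUATION.ranking_iterations,
        fraction=EVALUATION.ranking_fraction,
        alpha=EVALUATION.ranking_alpha,
        min_per_class=EVALUATION.ranking_min_per_class,
    )
    sources = {}
    site_map = {}
    for name in ("baseline", "week2", "early_change", "combined"):
        fm = attach_clinical(
            build_source(feats["baseline"], feats["week2"], name), labels, sites
        )
        sources[name] = (fm.values, fm.labels)
        site_map[name] = fm.sites

    spec = ModelSpec(inner_folds=EVALUATION.inner_folds, seed=SEED)
    grid = threshold_source_grid(
        sources, thresholds=EVALUATION.thresholds, spec=spec,
        k=EVALUATION.outer_folds, seed=SEED, **rank_kwargs,
    )
    grid.to_csv(RESULTS / "accuracy_grid.csv", float_format="%.1f")
    print("nested 10-fold balanced accuracy (feature count) by threshold x source:")
    print(grid.round(1))

    loso_rows = []
    for name, (values, lab) in sources.items():
        report = leave_one_site_out(
            values, lab, site_map[name],
            ModelSpec(inner_folds=EVALUATION.inner_folds, seed=SEED,
                      vote_threshold=EVALUATION.loso_threshold),
            seed=SEED, **rank_kwargs,
        )
        for row_name, row in report.table.iterrows():
            loso_rows.append({"source": name, "partition": row_name,
                              "n": row["n"],
                              "balanced_accuracy": row["balanced_accuracy"]})
    loso = pd.DataFrame(loso_rows)
    loso.to_csv(RESULTS / "loso.csv", index=False, float_format="%.1f")
    print(f"\nleave-one-site-out at T={EVALUATION.loso_threshold}:")
    print(loso.pivot(index="source", columns="partition",
                     values="balanced_accuracy").round(1))


if __name__ == "__main__":
    main()
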