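"""Rank every feature by subsample-voting, per feature source.

Builds the four feature sources (baseline, week 2, early change, combined),
runs the 100-iteration, 80%-subsample t-test voting against the responder
labels, writes one vote table per source to results/votes_{source}.csv, and
renders scale x electrode vote maps for the multiscale-entropy features
(results/figures/votemap_mse_{source}.png) to visualise where predictive
complexity features concentrate.
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import EVALUATION, MONTAGE, RESULTS, SCRATCH, SEED, ensure_dirs

from restpredict.assembly import attach_clinical, build_source, parse_key
from restpredict.clinical import labels_from_records, read_clinical_csv
from restpredict.ranking import rank_features


def vote_map(votes: pd.Series, source: str, out_path: Path) -> None:
    """Heat map of votes for entropy features: channels x scales."""
    rows = []
    for key, v in votes.items():
        d = parse_key(key)
        if d["class"] == "mse":
            rows.append((d["location"], int(d["band_or_scale"]), v))
    if not rows:
        return
    table = pd.DataFrame(rows, columns=["channel", "scale", "votes"])
    # the combined source carries both baseline- and early-change-tagged
    # copies of each (channel, scale); show the stronger of the two
    grid = table.pivot_table(
        index="channel", columns="scale", values="votes", aggfunc="max"
    )
    grid = grid.reindex([c for c in MONTAGE if c in grid.index])
    fig, ax = plt.subplots(figsize=(10, 3))
    im = ax.imshow(grid.to_numpy(), aspect="auto", cmap="viridis",
                   vmin=0, vmax=100)
    ax.set_yticks(range(len(grid.index)), grid.index)
    ax.set_xlabel("timescale")
    ax.set_title(f"entropy feature votes — {source} source")
    fig.colorbar(im, ax=ax, label="votes")
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)


def main() -> None:
    ensure_dirs()
    (RESULTS / "figures").mkdir(exist_ok=True)
    clinical = read_clinical_csv(RESULTS / "clinical.csv")
    labels = labels_from_records(clinical)
    sites = pd.Series({c.subject_id: c.site for c in clinical})
    feats = {
        tp: pd.read_csv(SCRATCH / f"features_{tp}.csv", index_col="subject_id")
        for tp in ("baseline", "week2")
    }

    for source in ("baseline", "week2", "early_change", "combined"):
        values = build_source(feats["baseline"], feats["week2"], source)
        fm = attach_clinical(values, labels, sites)
        table = rank_features(
            fm.values, fm.labels,
            n_iterations=EVALUATION.ranking_iterations,
            fraction=EVALUATION.ranking_fraction,
            alpha=EVALUATION.ranking_alpha,
            seed=SEED,
            min_per_class=EVALUATION.ranking_min_per_class,
        )
        table.to_csv(RESULTS / f"votes_{source}.csv")
        vote_map(table.votes, source, RESULTS / "figures" / f"votemap_mse_{source}.png")
        top = table.votes.sort_values(ascending=False).head(5)
        n60 = int((table.votes >= 60).sum())
        print(f"{source}: {n60} features with >= 60 votes; top:")
        for key, v in top.items():
            print(f"    {key}  {v}")


if __name__ == "__main__":
    main()
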