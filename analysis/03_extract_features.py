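"""Extract the four feature classes for every cleaned recording.

Electrode band powers and lateralization, ROI source band powers (eLORETA on
the synthetic-anatomy leadfield), 70-scale multiscale entropy and asymmetry,
and microstate statistics from a group-level 4-class model.  Writes
subjects x features tables per timepoint to scratch/analysis/features_{timepoint}.csv
(intermediate data; the small summary tables downstream go to results/).
"""

import sys
from collections import Counter
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import FEATURES, MONTAGE, RESULTS, SCRATCH, SEED, ensure_dirs

from restpredict.assembly import extract_features, parse_key
from restpredict.microstate import collect_peak_maps, fit_microstates
from restpredict.preprocess import load_epoched
from restpredict.source import elorata_inverse
from restpredict.synthdata import generate_leadfield


def main() -> None:
    ensure_dirs()
    clean_dir = SCRATCH / "clean"
    narrows = {}
    wides = {}
    for path in sorted(clean_dir.glob("*_narrow.h5")):
        rec = load_epoched(path)
        narrows[(rec.subject_id, rec.timepoint)] = rec
    for path in sorted(clean_dir.glob("*_wide.h5")):
        rec = load_epoched(path)
        wides[(rec.subject_id, rec.timepoint)] = rec

    leadfield = generate_leadfield(len(MONTAGE), FEATURES.n_sources, seed=SEED,
                                   n_rois=FEATURES.n_rois)
    leadfield.channels = list(MONTAGE)
    operator = elorata_inverse(leadfield, alpha=FEATURES.elorata_alpha)
    model = fit_microstates(
        collect_peak_maps(list(narrows.values())), k=FEATURES.microstate_k,
        n_restarts=FEATURES.microstate_restarts, seed=SEED,
    )
    print(f"group microstate model: k={model.k}, GEV={model.gev:.2f}")

    per_tp: dict[str, dict[str, pd.Series]] = {"baseline": {}, "week2": {}}
    for (sid, tp), narrow in narrows.items():
        per_tp[tp][sid] = extract_features(
            narrow, wides[(sid, tp)], mse_config=FEATURES.mse,
            microstate_model=model, inverse_operator=operator,
            roi_map=leadfield.roi_map,
        )

    for tp, series in per_tp.items():
        if not series:
            continue
        table = pd.DataFrame(series).T.sort_index()
        table.index.name = "subject_id"
        table.to_csv(SCRATCH / f"features_{tp}.csv", float_format="%.6g")
        counts = Counter(parse_key(k)["class"] for k in table.columns)
        print(f"{tp}: {table.shape[0]} subjects x {table.shape[1]} features "
              f"({dict(counts)})")


if __name__ == "__main__":
    main()
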