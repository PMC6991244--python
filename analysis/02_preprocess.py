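"""Harmonize and clean every recording into epoched form.

Each raw recording becomes two cleaned copies: a 1-30 Hz narrow-band version
(spectral, source, microstate features) and a 0.5-55 Hz wide-band version
(multiscale entropy).  Writes the cleaned containers under
scratch/analysis/clean and a per-recording quality-control table
(epochs kept/rejected) to results/preprocess_qc.csv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import COHORT, MONTAGE, PREPROCESS, RESULTS, SCRATCH, ensure_dirs

from restpredict.preprocess import (
    QualityError,
    load_continuous,
    preprocess_recording,
    save_epoched,
)


def main() -> None:
    ensure_dirs()
    clean_dir = SCRATCH / "clean"
    clean_dir.mkdir(exist_ok=True)
    rows = []
    for path in sorted((SCRATCH / "cohort").glob("*.h5")):
        raw = load_continuous(path)
        row = {"subject_id": raw.subject_id, "timepoint": raw.timepoint,
               "site": raw.site}
        try:
            for band, tag in ((PREPROCESS.narrow_band, "narrow"),
                              (PREPROCESS.wide_band, "wide")):
                cleaned = preprocess_recording(
                    raw, PREPROCESS.target_rate, list(MONTAGE),
                    PREPROCESS.line_freq, band, PREPROCESS.epoch_length,
                    PREPROCESS.peak_threshold_uv, PREPROCESS.min_epochs,
                )
                save_epoched(cleaned, clean_dir / f"{path.stem}_{tag}.h5")
                row[f"epochs_kept_{tag}"] = cleaned.n_epochs
                row[f"epochs_total_{tag}"] = cleaned.kept_epoch_mask.size
            row["excluded"] = False
        except QualityError as exc:
            row["excluded"] = True
            print(f"excluded {raw.subject_id}/{raw.timepoint}: {exc}")
        rows.append(row)

    qc = pd.DataFrame(rows)
    qc.to_csv(RESULTS / "preprocess_qc.csv", index=False)
    kept = (~qc["excluded"]).sum()
    print(f"cleaned {kept}/{len(qc)} recordings; "
          f"mean epochs kept {qc['epochs_kept_narrow'].mean():.1f}"
          f"/{qc['epochs_total_narrow'].mean():.0f}")


if __name__ == "__main__":
    main()
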