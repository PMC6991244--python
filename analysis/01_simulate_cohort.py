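"""Generate the synthetic multi-site cohort: recordings + clinical table.

Writes raw recordings (HDF5, large/binary) under scratch/analysis/cohort and
the clinical CSV + manifest under results/.  Prints the cohort summary table
(per-site counts, responder percentages, MADRS means) so the emulated
population can be eyeballed against the intended structure.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import COHORT, RESULTS, SCRATCH, ensure_dirs

from restpredict.clinical import cohort_summary, write_clinical_csv
from restpredict.synthdata import generate_cohort, write_cohort


def main() -> None:
    ensure_dirs()
    recordings, clinical = generate_cohort(COHORT)
    write_cohort(recordings, clinical, COHORT, SCRATCH / "cohort")
    write_clinical_csv(clinical, RESULTS / "clinical.csv")

    n_week2 = sum(r.timepoint == "week2" for r in recordings)
    print(f"generated {len(clinical)} subjects "
          f"({len(clinical)} baseline, {n_week2} week-2 recordings)")
    summary = cohort_summary(clinical)
    summary.to_csv(RESULTS / "cohort_summary.csv", float_format="%.2f")
    print(summary[["n", "n_responders", "pct_responders",
                   "madrs_baseline_mean", "madrs_week8_mean"]].round(1))


if __name__ == "__main__":
    main()
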