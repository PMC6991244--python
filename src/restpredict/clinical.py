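"""Clinical tables, MADRS change, and responder/nonresponder labeling.

The outcome of interest is antidepressant treatment response defined on the
Montgomery–Åsberg Depression Rating Scale (MADRS, 0–60 points): a subject is a
*responder* if their score decreased by at least 50% between the baseline and
week-8 visits, a *nonresponder* otherwise.  Subjects without a week-8 score
cannot be labeled and are excluded from all modeling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: MADRS decrease (percent of baseline) at or above which a subject is a responder.
RESPONSE_THRESHOLD_PCT = 50.0

CLINICAL_COLUMNS = [
    "subject_id",
    "site",
    "age",
    "sex",
    "madrs_baseline",
    "madrs_week2",
    "madrs_week8",
]


class UndefinedLabelError(ValueError):
    """Raised when a responder label cannot be derived for a subject."""


@dataclass
class ClinicalRecord:
    """One subject's demographics and MADRS scores across the three visits.

    ``madrs_week2`` and ``madrs_week8`` may be ``None`` (missing visit); a
    missing week-8 score makes the outcome label undefined.
    """

    subject_id: str
    site: str
    age: float
    sex: str
    madrs_baseline: float
    madrs_week2: Optional[float] = None
    madrs_week8: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("madrs_baseline", "madrs_week2", "madrs_week8"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 60.0):
                raise ValueError(f"{name}={v!r} outside the MADRS range [0, 60]")


def percent_decrease(baseline: float, week8: float) -> float:
    """MADRS decrease from baseline to week 8 as a percentage of baseline.

    Negative values mean the score *increased* (worsening).

    Raises
    ------
    UndefinedLabelError
        If ``baseline <= 0`` (percent change undefined) or either score is
        missing/non-finite.
    """
    if baseline is None or week8 is None:
        raise UndefinedLabelError("missing MADRS score")
    if not (math.isfinite(baseline) and math.isfinite(week8)):
        raise UndefinedLabelError("non-finite MADRS score")
    if baseline <= 0:
        raise UndefinedLabelError(f"baseline MADRS must be > 0, got {baseline}")
    return 100.0 * (baseline - week8) / baseline


def label_responder(baseline: float, week8: float) -> str:
    """Assign ``"responder"`` / ``"nonresponder"`` from baseline and week-8 MADRS.

    The boundary is inclusive: a decrease of exactly 50% counts as response.
    """
    return (
        "responder"
        if percent_decrease(baseline, week8) >= RESPONSE_THRESHOLD_PCT
        else "nonresponder"
    )


def labels_from_records(records: Iterable[ClinicalRecord]) -> pd.Series:
    """Responder labels for every labelable subject, indexed by subject id.

    Subjects with a missing week-8 score (or baseline 0) are silently dropped,
    with a log entry giving the count.
    """
    out: dict[str, str] = {}
    n_dropped = 0
    for rec in records:
        try:
            out[rec.subject_id] = label_responder(rec.madrs_baseline, rec.madrs_week8)
        except UndefinedLabelError:
            n_dropped += 1
    if n_dropped:
        logger.info("dropped %d subjects without a definable outcome label", n_dropped)
    return pd.Series(out, name="label", dtype="object")


def cohort_summary(records: list[ClinicalRecord]) -> pd.DataFrame:
    """Per-site and overall cohort summary.

    One row per site plus an ``All`` row with: subject count, responder count
    and percentage (1 decimal), mean (SD) MADRS at each visit, and mean (SD)
    absolute and percent decreases.  Empty site strata are omitted with a
    logged warning; subjects without labels contribute to the score summaries
    but not to responder counts.
    """
    if not records:
        raise ValueError("cohort_summary requires a non-empty record list")

    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "site": [r.site for r in records],
            "madrs_baseline": [r.madrs_baseline for r in records],
            "madrs_week2": [r.madrs_week2 for r in records],
            "madrs_week8": [r.madrs_week8 for r in records],
        }
    ).astype({"madrs_baseline": float})
    df["madrs_week2"] = pd.to_numeric(df["madrs_week2"])
    df["madrs_week8"] = pd.to_numeric(df["madrs_week8"])

    def _one(group: pd.DataFrame, name: str) -> dict:
        labeled = group.dropna(subset=["madrs_week8"])
        labeled = labeled[labeled["madrs_baseline"] > 0]
        resp = sum(
            label_responder(b, w) == "responder"
            for b, w in zip(labeled["madrs_baseline"], labeled["madrs_week8"])
        )
        n_labeled = len(labeled)
        dec = labeled["madrs_baseline"] - labeled["madrs_week8"]
        dec_pct = 100.0 * dec / labeled["madrs_baseline"]
        return {
            "site": name,
            "n": len(group),
            "n_responders": resp,
            "pct_responders": round(100.0 * resp / n_labeled, 1) if n_labeled else np.nan,
            "madrs_baseline_mean": group["madrs_baseline"].mean(),
            "madrs_baseline_sd": group["madrs_baseline"].std(),
            "madrs_week2_mean": group["madrs_week2"].mean(),
            "madrs_week2_sd": group["madrs_week2"].std(),
            "madrs_week8_mean": group["madrs_week8"].mean(),
            "madrs_week8_sd": group["madrs_week8"].std(),
            "decrease_mean": dec.mean(),
            "decrease_sd": dec.std(),
            "decrease_pct_mean": dec_pct.mean(),
            "decrease_pct_sd": dec_pct.std(),
        }

    rows = []
    for site, group in df.groupby("site", sort=True):
        if group.empty:  # pragma: no cover - groupby never yields empty groups
            logger.warning("site %s has no subjects; omitted from summary", site)
            continue
        rows.append(_one(group, str(site)))
    rows.append(_one(df, "All"))
    return pd.DataFrame(rows).set_index("site")


def read_clinical_csv(path) -> list[ClinicalRecord]:
    """Read the clinical table (strict header check; empty fields = missing)."""
    df = pd.read_csv(path, dtype={"subject_id": str, "site": str, "sex": str})
    if list(df.columns) != CLINICAL_COLUMNS:
        raise ValueError(
            f"clinical CSV must have columns {CLINICAL_COLUMNS}, got {list(df.columns)}"
        )
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ClinicalRecord(
                subject_id=row.subject_id,
                site=row.site,
                age=float(row.age),
                sex=row.sex,
                madrs_baseline=float(row.madrs_baseline),
                madrs_week2=None if pd.isna(row.madrs_week2) else float(row.madrs_week2),
                madrs_week8=None if pd.isna(row.madrs_week8) else float(row.madrs_week8),
            )
        )
    return records


def write_clinical_csv(records: Iterable[ClinicalRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "site": r.site,
                "age": r.age,
                "sex": r.sex,
                "madrs_baseline": r.madrs_baseline,
                "madrs_week2": r.madrs_week2,
                "madrs_week8": r.madrs_week8,
            }
            for r in records
        ],
        columns=CLINICAL_COLUMNS,
    )
    df.to_csv(path, index=False)
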