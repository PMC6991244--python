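"""Per-subject feature vectors and the four feature sources.

Every feature carries a descriptor key ``class|location|band_or_scale`` with
class in {spectral, spectral_asym, mse, mse_asym, microstate, source}.  When
features from the two recording timepoints are combined into a *feature
source* — baseline, week 2, early change (week-2 minus baseline), or
combined (baseline union early change) — a ``source_tag`` field is appended
to the key, keeping column keys unique.

Standardisation is deliberately deferred to model evaluation (fitted on
training data only) so that no statistic of held-out subjects leaks into
training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import spectral as spec_mod
from .entropy import MSEConfig, entropy_asymmetry, mse_curve
from .microstate import MicrostateModel, backfit_and_stats
from .preprocess import EpochedRecording
from .source import InverseOperator, source_band_power
from .spectral import BandGrid, lateralization
from .synthdata import homologue_pairs

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("spectral", "spectral_asym", "mse", "mse_asym", "microstate", "source")
SOURCES = ("baseline", "week2", "early_change", "combined")


def parse_key(key: str) -> dict[str, str]:
    parts = key.split("|")
    if len(parts) == 3:
        cls, loc, band_or_scale = parts
        tag = ""
    elif len(parts) == 4:
        cls, loc, band_or_scale, tag = parts
    else:
        raise ValueError(f"malformed feature key {key!r}")
    return {"class": cls, "location": loc, "band_or_scale": band_or_scale, "source_tag": tag}


def descriptor_table(columns: list[str]) -> pd.DataFrame:
    """Descriptor side-table (class/location/band-or-scale/source_tag) for keys."""
    return pd.DataFrame([parse_key(k) for k in columns], index=pd.Index(columns, name="key"))


@dataclass
class FeatureMatrix:
    """Subjects x features with aligned descriptors, labels and sites."""

    values: pd.DataFrame
    labels: pd.Series | None = None
    sites: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature keys: {dupes[:5]}")
        for aligned in (self.labels, self.sites):
            if aligned is not None and not aligned.index.equals(self.values.index):
                raise ValueError("labels/sites index must align with subjects")

    @property
    def descriptors(self) -> pd.DataFrame:
        return descriptor_table(list(self.values.columns))

    def to_csv(self, values_path, descriptors_path=None) -> None:
        out = self.values.copy()
        out.index.name = "subject_id"
        if self.labels is not None:
            out.insert(0, "label", self.labels)
        if self.sites is not None:
            out.insert(0, "site", self.sites)
        out.to_csv(values_path)
        if descriptors_path is not None:
            self.descriptors.to_csv(descriptors_path)

    @classmethod
    def from_csv(cls, values_path) -> "FeatureMatrix":
        df = pd.read_csv(values_path, index_col="subject_id")
        labels = df.pop("label") if "label" in df.columns else None
        sites = df.pop("site") if "site" in df.columns else None
        return cls(values=df, labels=labels, sites=sites)


# ---------------------------------------------------------------------------
# Per-subject feature extraction


def extract_features(
    narrowband: EpochedRecording,
    wideband: EpochedRecording | None = None,
    grid: BandGrid = BandGrid(),
    mse_config: MSEConfig = MSEConfig(),
    microstate_model: MicrostateModel | None = None,
    inverse_operator: InverseOperator | None = None,
    roi_map: dict[str, np.ndarray] | None = None,
) -> pd.Series:
    """All feature classes for one subject/timepoint -> key-indexed Series.

    ``narrowband`` (1-30 Hz) feeds spectral, source, and microstate features;
    ``wideband`` (default: the same recording) feeds multiscale entropy.
    Band powers are log10-transformed; lateralization/asymmetry indices are
    computed on the raw (untransformed) non-negative quantities.
    """
    wide = wideband if wideband is not None else narrowband
    channels = narrowband.channels
    pairs = homologue_pairs(channels)
    out: dict[str, float] = {}

    # class 1: electrode-level band power + lateralization
    powers = spec_mod.band_power_table(narrowband, grid)
    ch_index = {c: i for i, c in enumerate(channels)}
    for band, vec in powers.items():
        for ch, v in zip(channels, vec):
            out[f"spectral|{ch}|{band}"] = float(np.log10(v)) if v > 0 else np.nan
        for left, right in pairs:
            out[f"spectral_asym|{left}-{right}|{band}"] = lateralization(
                float(vec[ch_index[left]]), float(vec[ch_index[right]])
            )

    # class 3: multiscale entropy on the concatenated clean wideband signal
    concat = wide.concatenated()
    curves: dict[str, np.ndarray] = {}
    for ch in channels:
        curve = mse_curve(concat[wide.channels.index(ch)], mse_config)
        curves[ch] = curve
        for s, v in enumerate(curve, start=1):
            out[f"mse|{ch}|{s:02d}"] = float(v)
    for left, right in pairs:
        asym = entropy_asymmetry(curves[left], curves[right])
        for s, v in enumerate(asym, start=1):
            out[f"mse_asym|{left}-{right}|{s:02d}"] = float(v)

    # class 2: source-space band power (synthetic-anatomy leadfield unless
    # the user supplies one)
    if inverse_operator is not None and roi_map is not None:
        sbp = source_band_power(narrowband, inverse_operator, roi_map, grid)
        for (roi, band), v in sbp.items():
            out[f"source|{roi}|{band}"] = float(np.log10(v)) if v > 0 else np.nan

    # class 4: microstate statistics from a (group-level) fitted model
    if microstate_model is not None:
        stats = backfit_and_stats(microstate_model, narrowband)
        k = microstate_model.k
        for c in range(k):
            out[f"microstate|global|duration_{c}"] = float(stats[f"duration_{c}"])
            out[f"microstate|global|occurrence_{c}"] = float(stats[f"occurrence_{c}"])
            out[f"microstate|global|coverage_{c}"] = float(stats[f"coverage_{c}"])
        trans = stats["transitions"]
        for a in range(k):
            for b in range(k):
                if a != b:
                    out[f"microstate|global|trans_{a}_{b}"] = float(trans[a, b])

    return pd.Series(out, name=narrowband.subject_id)


# ---------------------------------------------------------------------------
# Feature sources


def build_source(
    features_baseline: pd.DataFrame,
    features_week2: pd.DataFrame | None,
    source: str,
) -> pd.DataFrame:
    """Assemble one of the four feature sources.

    ``features_baseline``/``features_week2`` are subjects x features tables
    with identical (untagged) feature keys.  The baseline source keeps all
    subjects; week2 / early_change / combined are restricted to subjects
    having week-2 data.  Early change is the raw week-2 minus baseline
    difference per feature; combined is the column-wise union of baseline and
    early-change features, distinguished by source tag.
    """
    if source not in SOURCES:
        raise ValueError(f"unknown feature source {source!r}; expected one of {SOURCES}")
    if source == "baseline":
        return features_baseline.add_suffix("|baseline").sort_index()
    if features_week2 is None:
        raise ValueError(f"feature source {source!r} requires week-2 features")

    common = features_week2.index.intersection(features_baseline.index)
    dropped = features_week2.index.difference(features_baseline.index)
    if len(dropped):
        logger.info("dropping %d subjects missing baseline features", len(dropped))
    week2 = features_week2.loc[common].sort_index()
    base = features_baseline.loc[common].sort_index()

    if source == "week2":
        return week2.add_suffix("|week2")
    change = (week2 - base[week2.columns]).add_suffix("|early_change")
    if source == "early_change":
        return change
    return pd.concat([base.add_suffix("|baseline"), change], axis=1)


def attach_clinical(
    values: pd.DataFrame, labels: pd.Series, sites: pd.Series
) -> FeatureMatrix:
    """Align a feature table with clinical labels/sites, dropping unlabeled rows."""
    idx = values.index.intersection(labels.index)
    n_dropped = len(values.index) - len(idx)
    if n_dropped:
        logger.info("dropping %d subjects without outcome labels", n_dropped)
    return FeatureMatrix(
        values=values.loc[idx], labels=labels.loc[idx], sites=sites.loc[idx]
    )
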