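"""Synthetic multi-site resting-state EEG cohorts with known ground truth.

The generator emulates the structure of a multicenter antidepressant-trial
EEG cohort: 122 subjects spread unevenly over four recording sites
(52/45/18/7), about 45% of whom respond to treatment (MADRS decrease >= 50%
by week 8), with week-2 recordings available for 115 of the 122.  Each
subject contributes a baseline recording and (usually) a week-2 recording.

Signal model, per channel: a 1/f background (spectral exponent ~1),
band-limited oscillators (alpha strongest over posterior electrodes), and
white sensor noise whose level and overall gain vary by site.  Ground-truth
group differences are injected either by scaling an oscillator's amplitude
inside a chosen frequency band (spectral effects) or by mixing in an
autocorrelated component that shifts sample entropy (complexity effects).
Week-2 recordings reuse the same subject-level parameters with fresh noise
plus any week-2-specific effects, so "early change" features have known
ground truth.

MADRS trajectories are drawn per group from truncated normals on the percent
decrease (responders centred above 50%, nonresponders below), and scores are
back-computed so that the >= 50% labeling rule reproduces the intended group
assignment exactly.

A separate feature-level generator (:func:`simulate_feature_cohort`)
produces subjects x features tables with effects of known standardised size
directly in feature space; it is used to calibrate the ranking and
evaluation machinery at exactly specified effect sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clinical import ClinicalRecord, write_clinical_csv
from .preprocess import ContinuousRecording, save_continuous
from .source import Leadfield
from .spectral import DEFAULT_BANDS

#: 19-channel 10-20 montage (left/right homologue pairs plus midline).
DEFAULT_MONTAGE = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
]

POSTERIOR_PREFIXES = ("P", "O")


class ConfigurationError(ValueError):
    pass


def homologue_pairs(montage: list[str]) -> list[tuple[str, str]]:
    """(left, right) electrode pairs: odd-numbered labels pair with even.

    Raises :class:`ConfigurationError` if a left channel lacks its right
    homologue.
    """
    labels = set(montage)
    pairs = []
    for ch in montage:
        if ch[-1].isdigit():
            n = int(ch[-1])
            if n % 2 == 1:  # left hemisphere
                right = ch[:-1] + str(n + 1)
                if right not in labels:
                    raise ConfigurationError(f"left channel {ch} lacks homologue {right}")
                pairs.append((ch, right))
    return pairs


@dataclass(frozen=True)
class EffectSpec:
    """A ground-truth responder/nonresponder difference to inject.

    ``feature_class`` is ``"band_power"`` (scale an oscillator inside
    ``band``) or ``"mse"`` (shift the weight of an autocorrelated component
    over the scale range ``scales``).  ``effect_size`` is the standardised
    mean difference (Cohen's d) between responders and nonresponders of the
    underlying subject-level parameter.
    """

    feature_class: str
    channels: tuple[str, ...]
    effect_size: float
    band: str | None = None
    scales: tuple[int, int] | None = None
    timepoints: tuple[str, ...] = ("baseline", "week2")

    def __post_init__(self) -> None:
        if self.feature_class not in ("band_power", "mse"):
            raise ConfigurationError(f"unknown feature_class {self.feature_class!r}")
        if not np.isfinite(self.effect_size):
            raise ConfigurationError("effect_size must be finite")
        if self.feature_class == "band_power" and self.band not in DEFAULT_BANDS:
            raise ConfigurationError(f"unknown band {self.band!r}")
        for tp in self.timepoints:
            if tp not in ("baseline", "week2"):
                raise ConfigurationError(f"unknown timepoint {tp!r}")


@dataclass(frozen=True)
class SiteEffects:
    """Per-site hardware differences: multiplicative gain, additive noise floor."""

    gains: tuple[float, ...] = (1.0, 1.15, 0.9, 1.05)
    noise_floors_uv: tuple[float, ...] = (2.0, 3.0, 1.5, 2.5)


@dataclass(frozen=True)
class MADRSModel:
    """Generative model for MADRS trajectories (points on the 0-60 scale).

    Percent decreases are truncated normals: responders on [50, 100],
    nonresponders on (-40, 50).  ``week2_fraction`` is the share of the total
    decrease realised by week 2, with ``week2_noise_sd`` points of noise.
    """

    baseline_mean: float = 30.1
    baseline_sd: float = 5.8
    responder_pct_mean: float = 73.3
    responder_pct_sd: float = 16.0
    nonresponder_pct_mean: float = 20.4
    nonresponder_pct_sd: float = 21.6
    week2_fraction: float = 0.5
    week2_noise_sd: float = 3.0


@dataclass(frozen=True)
class CohortConfig:
    """Full description of a synthetic cohort; all defaults mirror the
    emulated 122-subject, four-site study population."""

    n_subjects: int = 122
    site_sizes: tuple[int, ...] = (52, 45, 18, 7)
    site_names: tuple[str, ...] = ("UBC", "TGH", "QNS", "CAM")
    responder_fraction: float = 55 / 122
    week2_missing_fraction: float = 7 / 122
    sampling_rate: float = 250.0
    duration: float = 60.0
    montage: tuple[str, ...] = tuple(DEFAULT_MONTAGE)
    effects: tuple[EffectSpec, ...] = ()
    site_effects: SiteEffects = SiteEffects()
    madrs_model: MADRSModel = MADRSModel()
    artifact_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.site_sizes) != self.n_subjects:
            raise ConfigurationError(
                f"site_sizes {self.site_sizes} sum to {sum(self.site_sizes)}, "
                f"not n_subjects={self.n_subjects}"
            )
        if len(self.site_sizes) != len(self.site_names):
            raise ConfigurationError("site_sizes and site_names lengths differ")
        if not (0.0 < self.responder_fraction < 1.0):
            raise ConfigurationError("responder_fraction must be in (0, 1)")
        if not (0.0 <= self.week2_missing_fraction < 1.0):
            raise ConfigurationError("week2_missing_fraction must be in [0, 1)")
        homologue_pairs(list(self.montage))  # validates the montage
        for eff in self.effects:
            unknown = set(eff.channels) - set(self.montage)
            if unknown:
                raise ConfigurationError(f"effect channels {unknown} not in montage")


# ---------------------------------------------------------------------------
# Group / site assignment


def _apportion(total: int, weights: list[int]) -> list[int]:
    """Largest-remainder apportionment of ``total`` over ``weights``."""
    w = np.asarray(weights, dtype=float)
    quota = total * w / w.sum()
    out = np.floor(quota).astype(int)
    rem = total - out.sum()
    order = np.argsort(-(quota - out))
    out[order[:rem]] += 1
    return out.tolist()


def _truncnorm(rng, mean, sd, lo, hi, size):
    from scipy import stats

    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _madrs_trajectories(rng, model: MADRSModel, responder: np.ndarray):
    n = responder.size
    baseline = _truncnorm(rng, model.baseline_mean, model.baseline_sd, 12.0, 55.0, n)
    pct = np.empty(n)
    n_resp = int(responder.sum())
    pct[responder] = _truncnorm(
        rng, model.responder_pct_mean, model.responder_pct_sd, 50.0, 100.0, n_resp
    )
    pct[~responder] = _truncnorm(
        rng, model.nonresponder_pct_mean, model.nonresponder_pct_sd, -40.0, 50.0 - 1e-9,
        n - n_resp,
    )
    week8 = baseline * (1.0 - pct / 100.0)
    week2 = baseline - model.week2_fraction * (baseline - week8)
    week2 = week2 + rng.normal(0.0, model.week2_noise_sd, n)
    return baseline, np.clip(week2, 0.0, 60.0), np.clip(week8, 0.0, 60.0)


# ---------------------------------------------------------------------------
# Signal synthesis


def _pink_noise(rng, n_samples: int, fs: float, exponent: float = 1.0) -> np.ndarray:
    """1/f^exponent background, unit RMS."""
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    spectrum = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spectrum * scale, n=n_samples)
    return x / x.std()


def _ar1(rng, n_samples: int, phi: float = 0.97) -> np.ndarray:
    """Unit-RMS AR(1) series (strongly autocorrelated, low sample entropy)."""
    from scipy.signal import lfilter

    x = lfilter([1.0], [1.0, -phi], rng.standard_normal(n_samples))
    return x / x.std()


@dataclass
class _SubjectParams:
    """Per-subject latent signal parameters, shared across timepoints."""

    alpha_freq: float
    alpha_log_amp: float  # log10 of posterior-alpha amplitude factor
    effect_log_amps: dict[int, float]  # effect index -> log10 amp factor
    effect_mse_weights: dict[int, float]  # effect index -> AR mixing weight
    bg_rms: float


#: base amplitudes, microvolts
_BG_RMS = 8.0
_ALPHA_AMP = 6.0
_EFFECT_OSC_AMP = 5.0
_SUBJECT_LOG_SD = 0.15  # between-subject SD of log10 oscillator amplitude
_MSE_WEIGHT_MEAN = 0.35
_MSE_WEIGHT_SD = 0.08


def _draw_subject_params(rng, config: CohortConfig, is_responder: bool) -> _SubjectParams:
    effect_log_amps = {}
    effect_mse_weights = {}
    for i, eff in enumerate(config.effects):
        # Half the standardized shift goes to each group, with opposite sign,
        # so the between-group difference is d times the subject-level SD.
        shift = 0.5 * eff.effect_size * (1 if is_responder else -1)
        if eff.feature_class == "band_power":
            effect_log_amps[i] = _SUBJECT_LOG_SD * (rng.standard_normal() + shift)
        else:
            effect_mse_weights[i] = np.clip(
                _MSE_WEIGHT_MEAN + _MSE_WEIGHT_SD * (rng.standard_normal() + shift),
                0.0,
                0.9,
            )
    return _SubjectParams(
        alpha_freq=rng.uniform(9.5, 10.5),
        alpha_log_amp=_SUBJECT_LOG_SD * rng.standard_normal(),
        effect_log_amps=effect_log_amps,
        effect_mse_weights=effect_mse_weights,
        bg_rms=_BG_RMS * 10 ** (0.05 * rng.standard_normal()),
    )


def _synthesize_recording(
    rng,
    config: CohortConfig,
    params: _SubjectParams,
    timepoint: str,
    site_index: int,
    subject_id: str,
    site: str,
) -> ContinuousRecording:
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs
    montage = list(config.montage)
    gain = config.site_effects.gains[site_index % len(config.site_effects.gains)]
    noise_floor = config.site_effects.noise_floors_uv[
        site_index % len(config.site_effects.noise_floors_uv)
    ]

    data = np.empty((len(montage), n))
    for ci, ch in enumerate(montage):
        x = params.bg_rms * _pink_noise(rng, n, fs)
        # resting alpha, strongest posteriorly
        alpha_scale = 2.0 if ch.startswith(POSTERIOR_PREFIXES) else 1.0
        amp = _ALPHA_AMP * alpha_scale * 10**params.alpha_log_amp
        x = x + amp * np.sin(2 * np.pi * params.alpha_freq * t + rng.uniform(0, 2 * np.pi))

        for i, eff in enumerate(config.effects):
            if timepoint not in eff.timepoints or ch not in eff.channels:
                continue
            if eff.feature_class == "band_power":
                lo, hi = DEFAULT_BANDS[eff.band]
                f = 0.5 * (lo + hi)
                amp_i = _EFFECT_OSC_AMP * 10 ** params.effect_log_amps[i]
                x = x + amp_i * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            else:  # mse: blend in an autocorrelated (low-entropy) component
                w = params.effect_mse_weights[i]
                rms = x.std()
                x = (1.0 - w) * x + w * rms * _ar1(rng, n)

        x = x + noise_floor * rng.standard_normal(n)
        data[ci] = gain * x

    if rng.uniform() < config.artifact_rate:
        # amplitude outlier: a 0.5 s, ~150 uV burst on one channel
        start = rng.integers(0, max(1, n - int(0.5 * fs)))
        ch = rng.integers(0, len(montage))
        data[ch, start : start + int(0.5 * fs)] += 150.0

    return ContinuousRecording(
        subject_id=subject_id,
        site=site,
        timepoint=timepoint,
        sampling_rate=fs,
        channels=montage,
        data=data,
    )


# ---------------------------------------------------------------------------
# Public generators


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[ContinuousRecording], list[ClinicalRecord]]:
    """Generate raw recordings and clinical records for a synthetic cohort.

    Returns one baseline recording per subject plus week-2 recordings for
    exactly ``round((1 - week2_missing_fraction) * n)`` subjects, and one
    clinical record per subject whose MADRS scores reproduce the intended
    responder assignment under the >= 50% decrease rule.  Bit-identical for
    identical seeds.
    """
    root = np.random.SeedSequence(config.seed)
    ss_assign, ss_clin, ss_subjects = root.spawn(3)
    rng_assign = np.random.default_rng(ss_assign)

    # site + responder assignment
    sites: list[str] = []
    site_idx: list[int] = []
    for i, (name, size) in enumerate(zip(config.site_names, config.site_sizes)):
        sites += [name] * size
        site_idx += [i] * size
    n = config.n_subjects
    n_resp = int(round(config.responder_fraction * n))
    per_site_resp = _apportion(n_resp, list(config.site_sizes))
    responder = np.zeros(n, dtype=bool)
    offset = 0
    for size, k in zip(config.site_sizes, per_site_resp):
        chosen = rng_assign.choice(size, size=k, replace=False)
        responder[offset + chosen] = True
        offset += size

    n_week2 = int(round((1.0 - config.week2_missing_fraction) * n))
    has_week2 = np.zeros(n, dtype=bool)
    has_week2[rng_assign.choice(n, size=n_week2, replace=False)] = True

    # clinical records
    rng_clin = np.random.default_rng(ss_clin)
    baseline, week2, week8 = _madrs_trajectories(rng_clin, config.madrs_model, responder)
    ages = np.clip(rng_clin.normal(36.3, 12.7, n), 18, 60)
    sexes = np.where(rng_clin.uniform(size=n) < 76 / 122, "F", "M")

    clinical: list[ClinicalRecord] = []
    recordings: list[ContinuousRecording] = []
    subject_seeds = ss_subjects.spawn(n)
    for i in range(n):
        sid = f"sub-{i + 1:04d}"
        clinical.append(
            ClinicalRecord(
                subject_id=sid,
                site=sites[i],
                age=float(ages[i]),
                sex=str(sexes[i]),
                madrs_baseline=float(baseline[i]),
                madrs_week2=float(week2[i]) if has_week2[i] else None,
                madrs_week8=float(week8[i]),
            )
        )
        rng_subj = np.random.default_rng(subject_seeds[i])
        params = _draw_subject_params(rng_subj, config, bool(responder[i]))
        recordings.append(
            _synthesize_recording(
                rng_subj, config, params, "baseline", site_idx[i], sid, sites[i]
            )
        )
        if has_week2[i]:
            recordings.append(
                _synthesize_recording(
                    rng_subj, config, params, "week2", site_idx[i], sid, sites[i]
                )
            )
    return recordings, clinical


def generate_leadfield(
    n_channels: int, n_sources: int, seed: int = 0, n_rois: int = 8
) -> Leadfield:
    """Random synthetic-anatomy leadfield: average-referenced, unit-norm columns.

    The gain matrix has full row rank up to the average-reference constraint
    (rank ``n_channels - 1``); sources are partitioned into ``n_rois``
    contiguous, generically named regions.  This is a synthetic stand-in for
    an anatomical head model and is labeled as such downstream.
    """
    if n_channels < 4:
        raise ConfigurationError("need at least 4 channels")
    if n_sources < n_channels:
        raise ConfigurationError(
            f"n_sources ({n_sources}) must be >= n_channels ({n_channels})"
        )
    rng = np.random.default_rng(seed)
    gain = rng.standard_normal((n_channels, n_sources))
    gain -= gain.mean(axis=0, keepdims=True)  # average reference
    gain /= np.linalg.norm(gain, axis=0, keepdims=True)
    bounds = np.linspace(0, n_sources, n_rois + 1).astype(int)
    roi_map = {
        f"region_{k:02d}": np.arange(bounds[k], bounds[k + 1]) for k in range(n_rois)
    }
    channels = [f"ch{i:02d}" for i in range(n_channels)]
    return Leadfield(gain=gain, channels=channels, roi_map=roi_map)


def simulate_feature_cohort(
    n_subjects: int = 120,
    n_noise_features: int = 100,
    n_effect_features: int = 0,
    effect_size: float = 0.0,
    responder_fraction: float = 0.5,
    site_sizes: tuple[int, ...] | None = None,
    site_names: tuple[str, ...] | None = None,
    site_shift_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Feature-space cohort: iid standard-normal features with known effects.

    The first ``n_effect_features`` columns carry a between-group mean shift
    of ``effect_size`` standard deviations (Cohen's d); the remaining columns
    are pure noise.  ``site_shift_sd`` adds a per-site, per-feature offset
    emulating site batch effects.  Returns (values, labels, sites) indexed by
    subject id.
    """
    rng = np.random.default_rng(seed)
    n_feat = n_noise_features + n_effect_features
    n_resp = int(round(responder_fraction * n_subjects))
    labels = np.array(["nonresponder"] * n_subjects, dtype=object)
    labels[rng.choice(n_subjects, size=n_resp, replace=False)] = "responder"

    if site_sizes is None:
        sites = np.array(["S1"] * n_subjects, dtype=object)
    else:
        if sum(site_sizes) != n_subjects:
            raise ConfigurationError("site_sizes must sum to n_subjects")
        names = site_names or tuple(f"S{i + 1}" for i in range(len(site_sizes)))
        sites = np.concatenate(
            [np.full(sz, nm, dtype=object) for nm, sz in zip(names, site_sizes)]
        )

    values = rng.standard_normal((n_subjects, n_feat))
    is_resp = labels == "responder"
    values[is_resp, :n_effect_features] += 0.5 * effect_size
    values[~is_resp, :n_effect_features] -= 0.5 * effect_size
    if site_shift_sd > 0:
        for nm in np.unique(sites):
            values[sites == nm] += site_shift_sd * rng.standard_normal(n_feat)

    ids = [f"sub-{i + 1:04d}" for i in range(n_subjects)]
    cols = [f"effect|f{i:03d}" for i in range(n_effect_features)] + [
        f"noise|f{i:03d}" for i in range(n_noise_features)
    ]
    return (
        pd.DataFrame(values, index=ids, columns=cols),
        pd.Series(labels, index=ids, name="label"),
        pd.Series(sites, index=ids, name="site"),
    )


def write_cohort(
    recordings: list[ContinuousRecording],
    clinical: list[ClinicalRecord],
    config: CohortConfig,
    out_dir,
) -> None:
    """Persist a cohort: one HDF5 container per recording, clinical CSV, manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        save_continuous(rec, out_dir / f"{rec.subject_id}_{rec.timepoint}.h5")
    write_clinical_csv(clinical, out_dir / "clinical.csv")
    from dataclasses import asdict

    manifest = {"config": asdict(config), "n_recordings": len(recordings)}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
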