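"""Synthetic cohort generator: structure, determinism, ground-truth effects."""

import numpy as np
import pytest
from scipy import stats

from restpredict.clinical import label_responder, labels_from_records
from restpredict.preprocess import epoch
from restpredict.spectral import DEFAULT_BANDS, band_power, psd
from restpredict.synthdata import (
    CohortConfig,
    ConfigurationError,
    EffectSpec,
    MADRSModel,
    generate_cohort,
    homologue_pairs,
    simulate_feature_cohort,
    write_cohort,
)

SMALL = dict(
    n_subjects=8,
    site_sizes=(5, 3),
    site_names=("A", "B"),
    responder_fraction=0.5,
    duration=4.0,
    montage=("O1", "O2", "Cz"),
    artifact_rate=0.0,
)


class TestConfigValidation:
    def test_site_sizes_must_sum(self):
        with pytest.raises(ConfigurationError, match="sum"):
            CohortConfig(n_subjects=10, site_sizes=(5, 4), site_names=("A", "B"))

    def test_responder_fraction_bounds(self):
        with pytest.raises(ConfigurationError, match="responder_fraction"):
            CohortConfig(**{**SMALL, "responder_fraction": 1.0})

    def test_montage_needs_homologues(self):
        with pytest.raises(ConfigurationError, match="homologue"):
            CohortConfig(**{**SMALL, "montage": ("O1", "Cz")})

    def test_effect_channels_must_be_in_montage(self):
        eff = EffectSpec("band_power", ("F3",), 1.0, band="theta")
        with pytest.raises(ConfigurationError, match="montage"):
            CohortConfig(**{**SMALL, "effects": (eff,)})

    def test_effect_size_must_be_finite(self):
        with pytest.raises(ConfigurationError, match="finite"):
            EffectSpec("band_power", ("O1",), float("inf"), band="theta")

    def test_homologue_pairs_found(self):
        pairs = homologue_pairs(["Fp1", "Fp2", "C3", "C4", "Cz"])
        assert pairs == [("Fp1", "Fp2"), ("C3", "C4")]


class TestCohortStructure:
    def test_counts_match_missingness_fraction(self):
        cfg = CohortConfig(
            n_subjects=122,
            site_sizes=(52, 45, 18, 7),
            week2_missing_fraction=7 / 122,
            duration=1.0,
            montage=("C3", "C4"),
            artifact_rate=0.0,
            seed=1,
        )
        recordings, clinical = generate_cohort(cfg)
        baselines = [r for r in recordings if r.timepoint == "baseline"]
        week2s = [r for r in recordings if r.timepoint == "week2"]
        assert len(baselines) == 122
        assert len(week2s) == 115
        assert len(clinical) == 122

    def test_labels_reproduce_intended_assignment(self):
        cfg = CohortConfig(**SMALL, seed=4)
        _, clinical = generate_cohort(cfg)
        labels = labels_from_records(clinical)
        assert len(labels) == 8
        assert (labels == "responder").sum() == 4  # round(0.5 * 8)
        # every label is consistent with the >= 50% decrease rule
        for rec in clinical:
            assert labels[rec.subject_id] == label_responder(
                rec.madrs_baseline, rec.madrs_week8
            )

    def test_same_seed_bit_identical(self):
        cfg = CohortConfig(**SMALL, seed=9)
        rec1, clin1 = generate_cohort(cfg)
        rec2, clin2 = generate_cohort(cfg)
        assert len(rec1) == len(rec2)
        for a, b in zip(rec1, rec2):
            np.testing.assert_array_equal(a.data, b.data)
        for a, b in zip(clin1, clin2):
            assert a == b

    def test_different_seed_differs(self):
        rec1, _ = generate_cohort(CohortConfig(**SMALL, seed=1))
        rec2, _ = generate_cohort(CohortConfig(**SMALL, seed=2))
        assert not np.allclose(rec1[0].data, rec2[0].data)

    def test_site_gain_scales_amplitude(self):
        from restpredict.synthdata import SiteEffects

        cfg = CohortConfig(
            **{**SMALL, "site_sizes": (4, 4)},
            site_effects=SiteEffects(gains=(1.0, 2.5), noise_floors_uv=(1.0, 1.0)),
            seed=0,
        )
        recordings, _ = generate_cohort(cfg)
        rms_a = np.mean([r.data.std() for r in recordings if r.site == "A"])
        rms_b = np.mean([r.data.std() for r in recordings if r.site == "B"])
        assert rms_b > 1.8 * rms_a

    def test_write_cohort(self, tmp_path):
        cfg = CohortConfig(**SMALL, seed=2)
        recordings, clinical = generate_cohort(cfg)
        write_cohort(recordings, clinical, cfg, tmp_path)
        assert (tmp_path / "clinical.csv").exists()
        assert (tmp_path / "manifest.json").exists()
        n_h5 = len(list(tmp_path.glob("*.h5")))
        assert n_h5 == len(recordings)


def _theta_power_o1(recording):
    ep = epoch(recording, 2.0)
    spectrum = psd(ep)
    return float(
        np.log10(band_power(spectrum, DEFAULT_BANDS["theta"])[recording.channels.index("O1")])
    )


class TestGroundTruthEffects:
    def test_injected_band_effect_recovered_within_tolerance(self):
        """A Cohen's d = 1 theta-power effect is recovered empirically
        within +-0.3 at n=200 (Monte Carlo over one large cohort)."""
        cfg = CohortConfig(
            n_subjects=200,
            site_sizes=(200,),
            site_names=("A",),
            responder_fraction=0.5,
            duration=16.0,
            montage=("O1", "O2"),
            artifact_rate=0.0,
            effects=(EffectSpec("band_power", ("O1", "O2"), 1.0, band="theta"),),
            seed=21,
        )
        recordings, clinical = generate_cohort(cfg)
        labels = labels_from_records(clinical)
        vals = {r.subject_id: _theta_power_o1(r) for r in recordings}
        x = np.array([vals[s] for s in labels.index[labels == "responder"]])
        y = np.array([vals[s] for s in labels.index[labels == "nonresponder"]])
        pooled_sd = np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2)
        d_hat = (x.mean() - y.mean()) / pooled_sd
        assert d_hat == pytest.approx(1.0, abs=0.3)

    def test_null_cohorts_calibrated_type_i_error(self):
        """With zero injected effects, a theta-power t-test is non-significant
        at alpha=0.01 in >= 97 of 100 seeded cohorts (binomial oracle:
        P(Bin(100, 0.01) <= 3) ~ 0.98)."""
        n_nonsig = 0
        for seed in range(100):
            cfg = CohortConfig(
                n_subjects=24,
                site_sizes=(24,),
                site_names=("A",),
                responder_fraction=0.5,
                duration=8.0,
                montage=("O1", "O2"),
                artifact_rate=0.0,
                seed=seed,
            )
            recordings, clinical = generate_cohort(cfg)
            labels = labels_from_records(clinical)
            vals = {r.subject_id: _theta_power_o1(r) for r in recordings}
            x = [vals[s] for s in labels.index[labels == "responder"]]
            y = [vals[s] for s in labels.index[labels == "nonresponder"]]
            p = stats.ttest_ind(x, y, equal_var=False).pvalue
            n_nonsig += p >= 0.01
        assert n_nonsig >= 97


class TestFeatureCohort:
    def test_effect_size_realised(self):
        vals, labels, _ = simulate_feature_cohort(
            4000, n_noise_features=1, n_effect_features=1, effect_size=1.5, seed=0
        )
        resp = vals.loc[labels == "responder", vals.columns[0]]
        non = vals.loc[labels == "nonresponder", vals.columns[0]]
        sd = np.sqrt((resp.var() + non.var()) / 2)
        assert (resp.mean() - non.mean()) / sd == pytest.approx(1.5, abs=0.1)

    def test_sites_and_determinism(self):
        v1, l1, s1 = simulate_feature_cohort(
            60, 10, site_sizes=(30, 30), site_names=("X", "Y"), seed=3
        )
        v2, _, _ = simulate_feature_cohort(
            60, 10, site_sizes=(30, 30), site_names=("X", "Y"), seed=3
        )
        assert (s1 == "X").sum() == 30
        np.testing.assert_array_equal(v1.to_numpy(), v2.to_numpy())
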