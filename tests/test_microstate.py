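"""Microstate segmentation: GFP, polarity-invariant k-means, statistics."""

import numpy as np
import pytest

from restpredict.microstate import (
    MicrostateModel,
    SegmentationError,
    backfit,
    backfit_and_stats,
    collect_peak_maps,
    fit_microstates,
    gfp,
    gfp_peaks,
    microstate_stats,
    smooth_labels,
)

from .conftest import make_epoched


def _orthogonal_topo_data(rng, n_samples=2000, n_ch=8, flip=False):
    """Alternating 100-sample segments of two orthogonal topographies + noise."""
    m1 = np.zeros(n_ch)
    m1[: n_ch // 2] = 1.0
    m1[n_ch // 2 :] = -1.0
    m2 = np.zeros(n_ch)
    m2[::2] = 1.0
    m2[1::2] = -1.0
    m1 /= np.linalg.norm(m1)
    m2 /= np.linalg.norm(m2)
    data = np.empty((n_ch, n_samples))
    amp = 1.0 + 0.5 * np.abs(np.sin(np.arange(n_samples) / 7.0))
    for s in range(0, n_samples, 100):
        which = (s // 100) % 2
        topo = m1 if which == 0 else m2
        sign = -1.0 if (flip and which == 0 and s > n_samples // 2) else 1.0
        data[:, s : s + 100] = sign * np.outer(topo, amp[s : s + 100])
    data += 0.02 * rng.standard_normal(data.shape)
    data -= data.mean(axis=0)
    return data, m1, m2


class TestGFP:
    def test_equal_channels_zero_after_average_reference(self):
        data = np.ones((4, 100))
        data -= data.mean(axis=0)
        np.testing.assert_allclose(gfp(data), 0.0)

    def test_single_sample_definition(self):
        col = np.array([[1.0], [-1.0], [0.0], [0.0]])
        assert gfp(col)[0] == pytest.approx(np.std([1, -1, 0, 0]))

    def test_homogeneous_scaling(self, rng):
        data = rng.standard_normal((5, 200))
        np.testing.assert_allclose(gfp(-3.0 * data), 3.0 * gfp(data))

    def test_zero_signal_no_peaks(self):
        assert gfp_peaks(np.zeros((4, 100))).size == 0


class TestFitMicrostates:
    def test_recovers_constructed_topographies(self, rng):
        data, m1, m2 = _orthogonal_topo_data(rng)
        peaks = data[:, gfp_peaks(data)].T
        model = fit_microstates(peaks, k=2, n_restarts=5, seed=0)
        corr = np.abs(model.maps @ np.stack([m1, m2]).T)  # fitted x true
        # each true map matched by exactly one fitted map
        assert corr.max(axis=0).min() >= 0.99

    def test_polarity_invariance(self, rng):
        data, _, _ = _orthogonal_topo_data(rng)
        flipped, _, _ = _orthogonal_topo_data(
            np.random.default_rng(12345), flip=True
        )
        p1 = data[:, gfp_peaks(data)].T
        p2 = flipped[:, gfp_peaks(flipped)].T
        m_a = fit_microstates(p1, k=2, n_restarts=5, seed=0)
        m_b = fit_microstates(p2, k=2, n_restarts=5, seed=0)
        match = np.abs(m_a.maps @ m_b.maps.T)
        assert match.max(axis=1).min() >= 0.99

    def test_k1_is_dominant_eigenvector(self, rng):
        data, _, _ = _orthogonal_topo_data(rng)
        peaks = data[:, gfp_peaks(data)].T
        model = fit_microstates(peaks, k=1, n_restarts=1, seed=0)
        cov = peaks.T @ peaks
        w, v = np.linalg.eigh(cov)
        assert abs(float(model.maps[0] @ v[:, -1])) >= 1 - 1e-9
        assert model.gev == pytest.approx(
            _polarity_gev(peaks, model.maps), rel=1e-9
        )

    def test_gev_nondecreasing_in_k(self, rng):
        data, _, _ = _orthogonal_topo_data(rng, n_samples=4000)
        peaks = data[:, gfp_peaks(data)].T
        gevs = [
            fit_microstates(peaks, k=k, n_restarts=5, seed=0).gev for k in (1, 2, 3)
        ]
        assert gevs[0] <= gevs[1] + 1e-9 and gevs[1] <= gevs[2] + 1e-9

    def test_insufficient_peaks(self, rng):
        with pytest.raises(SegmentationError, match="peak maps"):
            fit_microstates(rng.standard_normal((30, 8)), k=4)


def _polarity_gev(peaks, maps):
    g = np.linalg.norm(peaks, axis=1) / np.sqrt(peaks.shape[1])
    labels = np.argmax(np.abs(peaks @ maps.T), axis=1)
    assigned = maps[labels]
    norm = np.linalg.norm(peaks, axis=1)
    corr = np.abs(np.sum(peaks * assigned, axis=1)) / norm
    return float(np.sum((g * corr) ** 2) / np.sum(g**2))


class TestStats:
    def test_alternating_sequence_statistics(self):
        # A(100 ms) B(100 ms) alternating over 10 s at 250 Hz: 25-sample runs
        labels = np.tile(np.repeat([0, 1], 25), 50)
        stats = microstate_stats(labels, k=2, sampling_rate=250.0)
        assert stats["coverage_0"] == pytest.approx(0.5)
        assert stats["coverage_1"] == pytest.approx(0.5)
        assert stats["occurrence_0"] == pytest.approx(5.0)
        assert stats["duration_0"] == pytest.approx(100.0)
        trans = stats["transitions"]
        assert trans[0, 1] == 1.0 and trans[1, 0] == 1.0
        assert trans[0, 0] == 0.0 and trans[1, 1] == 0.0

    def test_coverage_sums_to_one(self, rng):
        labels = rng.integers(0, 4, size=1000)
        stats = microstate_stats(labels, k=4, sampling_rate=250.0)
        total = sum(stats[f"coverage_{c}"] for c in range(4))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_absent_class_is_flagged(self):
        labels = np.zeros(500, dtype=int)
        stats = microstate_stats(labels, k=3, sampling_rate=250.0)
        assert np.isnan(stats["duration_2"]) and stats["occurrence_2"] == 0.0

    def test_smoothing_removes_short_segments(self):
        labels = np.array([0] * 50 + [1] * 2 + [0] * 50)
        out = smooth_labels(labels, min_samples=5)
        assert np.all(out == 0)

    def test_stats_invariant_to_amplitude_scaling(self, rng):
        data, _, _ = _orthogonal_topo_data(rng)
        peaks = data[:, gfp_peaks(data)].T
        model = fit_microstates(peaks, k=2, n_restarts=3, seed=0)
        rec = make_epoched(data[None, :, :], sampling_rate=250.0)
        rec_scaled = make_epoched(5.0 * data[None, :, :], sampling_rate=250.0)
        s1 = backfit_and_stats(model, rec)
        s2 = backfit_and_stats(model, rec_scaled)
        for key in ("coverage_0", "duration_0", "occurrence_1"):
            assert s1[key] == pytest.approx(s2[key])
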