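"""EEG microstate segmentation and derived statistics.

Microstates are quasi-stable scalp potential topographies that dominate the
EEG for tens of milliseconds before switching.  Segmentation follows the
modified (polarity-invariant) k-means convention: class topographies are fit
to the maps at global-field-power (GFP) peaks, samples are assigned to the
class with the highest absolute spatial correlation, and each class map is
updated as the dominant eigenvector of the covariance of its assigned maps.
Quality is summarised by global explained variance (GEV).  Back-fitting a
model to a recording yields, per class: mean segment duration, occurrence
rate, time coverage, and the segment-level transition probability matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import EpochedRecording


class SegmentationError(ValueError):
    pass


@dataclass
class MicrostateModel:
    """Fitted microstate topographies (k x channels, unit-norm rows)."""

    maps: np.ndarray
    gev: float
    channels: list[str]

    @property
    def k(self) -> int:
        return self.maps.shape[0]


def gfp(data: np.ndarray) -> np.ndarray:
    """Global field power: per-sample SD of the (average-referenced) potentials.

    ``data`` is channels x samples.
    """
    data = np.asarray(data, dtype=np.float64)
    return data.std(axis=0)


def gfp_peaks(data: np.ndarray) -> np.ndarray:
    """Indices of local maxima of the GFP curve."""
    g = gfp(data)
    if np.allclose(g, 0.0):
        return np.array([], dtype=int)
    core = (g[1:-1] > g[:-2]) & (g[1:-1] >= g[2:])
    return np.flatnonzero(core) + 1


def _normalize_maps(maps: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(maps, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return maps / norms


def _gev(peak_maps: np.ndarray, g: np.ndarray, maps: np.ndarray, labels: np.ndarray) -> float:
    """Global explained variance of a labeling of GFP-peak maps."""
    # correlation of each peak map with its assigned template
    assigned = maps[labels]
    norm = np.linalg.norm(peak_maps, axis=1)
    norm[norm == 0] = 1.0
    corr = np.abs(np.sum(peak_maps * assigned, axis=1)) / norm
    return float(np.sum((g * corr) ** 2) / np.sum(g**2))


def fit_microstates(
    peak_maps: np.ndarray,
    k: int = 4,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 200,
    channels: list[str] | None = None,
) -> MicrostateModel:
    """Polarity-invariant modified k-means on GFP-peak maps.

    ``peak_maps`` is peaks x channels (average-referenced).  The best of
    ``n_restarts`` random initialisations by GEV is kept; deterministic given
    the seed.  Requires at least ``20 * k`` peak maps.
    """
    peak_maps = np.asarray(peak_maps, dtype=np.float64)
    n_peaks, n_ch = peak_maps.shape
    if n_peaks < 20 * k:
        raise SegmentationError(
            f"need at least {20 * k} GFP-peak maps to fit k={k}, got {n_peaks}"
        )
    g = np.linalg.norm(peak_maps, axis=1) / np.sqrt(n_ch)  # SD across channels
    rng = np.random.default_rng(seed)

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_restarts):
        maps = _normalize_maps(peak_maps[rng.choice(n_peaks, size=k, replace=False)].copy())
        labels = np.full(n_peaks, -1)
        for _ in range(max_iter):
            proj = peak_maps @ maps.T  # peaks x k
            new_labels = np.argmax(np.abs(proj), axis=1)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for j in range(k):
                members = peak_maps[labels == j]
                if members.shape[0] == 0:
                    # re-seed an empty class from a random peak map
                    members = peak_maps[rng.integers(n_peaks)][None, :]
                # dominant eigenvector of the members' covariance: polarity-
                # invariant mean topography
                cov = members.T @ members
                w, v = np.linalg.eigh(cov)
                maps[j] = v[:, -1]
            maps = _normalize_maps(maps)
        score = _gev(peak_maps, g, maps, labels)
        if best is None or score > best[0]:
            best = (score, maps.copy(), labels.copy())

    assert best is not None
    return MicrostateModel(maps=best[1], gev=best[0], channels=channels or [])


def backfit(model: MicrostateModel, data: np.ndarray) -> np.ndarray:
    """Assign every sample to its best microstate class (max |correlation|)."""
    proj = data.T @ model.maps.T  # samples x k
    return np.argmax(np.abs(proj), axis=1)


def smooth_labels(labels: np.ndarray, min_samples: int) -> np.ndarray:
    """Merge segments shorter than ``min_samples`` into the preceding segment."""
    labels = labels.copy()
    if min_samples <= 1 or labels.size == 0:
        return labels
    changed = True
    while changed:
        changed = False
        segs = _segments(labels)
        for i, (start, length, lab) in enumerate(segs):
            if length < min_samples and len(segs) > 1:
                if i > 0:
                    labels[start : start + length] = segs[i - 1][2]
                else:
                    labels[start : start + length] = segs[i + 1][2]
                changed = True
                break
    return labels


def _segments(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """(start, length, label) runs of a label sequence."""
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [(int(s), int(e - s), int(labels[s])) for s, e in zip(starts, ends)]


def microstate_stats(
    labels: np.ndarray, k: int, sampling_rate: float
) -> dict[str, float | np.ndarray]:
    """Duration / occurrence / coverage / transition statistics of a labeling.

    duration_<c>: mean segment duration, ms (NaN if the class never occurs);
    occurrence_<c>: segments per second; coverage_<c>: fraction of samples
    (sums to 1); ``transitions``: k x k matrix of segment-to-segment
    transition probabilities (rows sum to 1 where defined, NaN rows for
    classes that never occur).
    """
    segs = _segments(labels)
    total_s = labels.size / sampling_rate
    out: dict[str, float | np.ndarray] = {}
    counts = np.zeros(k)
    durs: list[list[float]] = [[] for _ in range(k)]
    for _, length, lab in segs:
        counts[lab] += 1
        durs[lab].append(length / sampling_rate * 1000.0)
    for c in range(k):
        out[f"duration_{c}"] = float(np.mean(durs[c])) if durs[c] else float("nan")
        out[f"occurrence_{c}"] = counts[c] / total_s
        out[f"coverage_{c}"] = float(np.sum(labels == c) / labels.size)
    trans = np.zeros((k, k))
    for (_, _, a), (_, _, b) in zip(segs[:-1], segs[1:]):
        trans[a, b] += 1
    row = trans.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        trans = np.where(row > 0, trans / row, np.nan)
    out["transitions"] = trans
    return out


def backfit_and_stats(
    model: MicrostateModel,
    epoched: EpochedRecording,
    min_duration_ms: float = 30.0,
) -> dict[str, float | np.ndarray]:
    """Back-fit a model to a recording and compute microstate statistics.

    Labels are smoothed by merging segments shorter than ``min_duration_ms``.
    Statistics are invariant to global amplitude scaling of the recording.
    """
    data = epoched.concatenated()
    if data.size == 0 or np.allclose(data, 0):
        raise SegmentationError("cannot back-fit a zero/empty recording")
    labels = backfit(model, data)
    min_samples = max(1, int(round(min_duration_ms / 1000.0 * epoched.sampling_rate)))
    labels = smooth_labels(labels, min_samples)
    return microstate_stats(labels, model.k, epoched.sampling_rate)


def collect_peak_maps(recordings: list[EpochedRecording]) -> np.ndarray:
    """Stack GFP-peak maps across recordings for group-level model fitting."""
    maps = []
    for rec in recordings:
        data = rec.concatenated()
        idx = gfp_peaks(data)
        if idx.size:
            maps.append(data[:, idx].T)
    if not maps:
        raise SegmentationError("no GFP peaks found in any recording")
    return np.concatenate(maps, axis=0)
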