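"""Electrode-level spectral features: band power and hemispheric lateralization.

Power spectral density is estimated by Welch's method with one Hann-windowed
segment per 2-s epoch, averaged across epochs (0.5 Hz resolution at the
250 Hz default rate).  Band power integrates the PSD over a fixed seven-band
grid spanning 1–30 Hz; lateralization of power for a homologous electrode
pair is the bounded, scale-free normalised difference (L - R) / (L + R).
Band powers are log10-transformed at the feature-assembly stage to stabilise
variance; the quantities here are in raw microvolt^2 units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate
from scipy import signal as sps

from .preprocess import EpochedRecording, QualityError

#: Canonical band grid (Hz).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.5),
    "theta": (4.0, 8.0),
    "low_alpha": (8.5, 10.0),
    "high_alpha": (10.5, 12.0),
    "low_beta": (12.5, 18.0),
    "middle_beta": (18.5, 21.0),
    "high_beta": (21.5, 30.0),
}


@dataclass(frozen=True)
class BandGrid:
    """Named, non-overlapping, ascending frequency bands."""

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )

    def __post_init__(self) -> None:
        prev_hi = -np.inf
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name}: lo must be < hi")
            if lo <= prev_hi:
                raise ValueError(f"band {name} overlaps or is out of order")
            prev_hi = hi

    def __iter__(self):
        return iter(self.bands.items())

    def __len__(self) -> int:
        return len(self.bands)


@dataclass
class PSD:
    """Welch PSD per channel: ``values`` is channels x frequencies, uV^2/Hz."""

    freqs: np.ndarray
    values: np.ndarray
    channels: list[str]


def psd(epoched: EpochedRecording, max_resolution_hz: float = 0.5) -> PSD:
    """Welch-average PSD over kept epochs, one Hann segment per epoch."""
    if epoched.n_epochs < 1:
        raise QualityError("PSD requires at least one kept epoch")
    n_per = epoched.data.shape[2]
    # One segment per epoch already gives epoch_length-limited resolution;
    # zero-pad if that resolution would be coarser than requested.
    nfft = n_per
    while epoched.sampling_rate / nfft > max_resolution_hz:
        nfft *= 2
    freqs, pxx = sps.welch(
        epoched.data,
        fs=epoched.sampling_rate,
        window="hann",
        nperseg=n_per,
        noverlap=0,
        nfft=nfft,
        axis=-1,
    )
    return PSD(freqs=freqs, values=pxx.mean(axis=0), channels=list(epoched.channels))


def band_power(spectrum: PSD, band: tuple[float, float]) -> np.ndarray:
    """Integral of the PSD over ``[lo, hi]`` per channel (trapezoid, uV^2)."""
    lo, hi = band
    if lo < spectrum.freqs[0] or hi > spectrum.freqs[-1]:
        raise ValueError(
            f"band [{lo}, {hi}] outside PSD range "
            f"[{spectrum.freqs[0]}, {spectrum.freqs[-1]}]"
        )
    sel = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
    if sel.sum() < 2:
        raise ValueError(f"band [{lo}, {hi}] narrower than the frequency resolution")
    return integrate.trapezoid(spectrum.values[:, sel], spectrum.freqs[sel], axis=-1)


def lateralization(left_value: float, right_value: float) -> float:
    """Normalised hemispheric difference ``(L - R) / (L + R)`` in [-1, 1].

    Returns NaN (feature missing) when both sides are zero.
    """
    if left_value < 0 or right_value < 0:
        raise ValueError("lateralization expects non-negative power values")
    total = left_value + right_value
    if total == 0:
        return float("nan")
    return (left_value - right_value) / total


def band_power_table(
    epoched: EpochedRecording, grid: BandGrid = BandGrid()
) -> dict[str, np.ndarray]:
    """Band power per channel for every band in the grid (band -> vector)."""
    spectrum = psd(epoched)
    return {name: band_power(spectrum, edges) for name, edges in grid}
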