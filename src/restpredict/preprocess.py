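"""Harmonization and cleaning of raw multi-site recordings.

Recordings acquired on heterogeneous hardware are converted to a common,
site-independent format: a shared sampling rate, a shared ordered 10–20
montage, and an average reference.  Power-line interference is removed with a
zero-phase band-stop filter, a band-pass restricts the analysis band, the
continuous record is cut into fixed-length epochs, and epochs containing
amplitude artifacts are rejected.  Two filtered copies are kept downstream:
a 1–30 Hz copy for spectral and microstate analysis and a wider 0.5–55 Hz
copy for entropy, which is sensitive to aggressive filtering.

On-disk container: HDF5 with datasets ``/data`` (epochs x channels x
samples, microvolts), ``/channels``, ``/mask`` and root attributes
``sampling_rate``, ``subject_id``, ``site``, ``timepoint``, ``epoch_length``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np
from scipy import signal as sps

DEFAULT_TARGET_RATE = 250.0
DEFAULT_EPOCH_LENGTH = 2.0
DEFAULT_PEAK_THRESHOLD_UV = 100.0
DEFAULT_MIN_EPOCHS = 15


class HarmonizationError(ValueError):
    """A raw recording cannot be mapped onto the target montage."""


class QualityError(ValueError):
    """Too little clean data survives for the subject to be usable."""


@dataclass
class ContinuousRecording:
    """Continuous multichannel EEG: channels x samples, microvolts."""

    subject_id: str
    site: str
    timepoint: str  # "baseline" | "week2"
    sampling_rate: float
    channels: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be channels x samples matching the montage")


@dataclass
class EpochedRecording:
    """Cleaned, epoched EEG: epochs x channels x samples, microvolts.

    ``kept_epoch_mask`` has one entry per *original* epoch; ``data`` holds
    only the surviving epochs, in order.
    """

    subject_id: str
    site: str
    timepoint: str
    sampling_rate: float
    channels: list[str]
    data: np.ndarray
    epoch_length: float
    kept_epoch_mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.kept_epoch_mask = np.asarray(self.kept_epoch_mask, dtype=bool)
        if self.data.ndim != 3 or self.data.shape[1] != len(self.channels):
            raise ValueError("data must be epochs x channels x samples")
        if self.data.shape[0] != int(self.kept_epoch_mask.sum()):
            raise ValueError("kept_epoch_mask inconsistent with epoch count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite samples after cleaning")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def concatenated(self) -> np.ndarray:
        """Channels x samples view of the kept epochs, concatenated in time."""
        return np.concatenate(list(self.data), axis=-1) if self.n_epochs else np.empty(
            (len(self.channels), 0)
        )


# ---------------------------------------------------------------------------
# Harmonization and filtering


def harmonize(
    recording: ContinuousRecording,
    target_rate: float = DEFAULT_TARGET_RATE,
    target_montage: list[str] | None = None,
) -> ContinuousRecording:
    """Resample, reorder/subset channels to the target montage, average-reference.

    Raises :class:`HarmonizationError` naming the first target channel absent
    from the input.
    """
    montage = list(target_montage) if target_montage is not None else list(recording.channels)
    index = {c: i for i, c in enumerate(recording.channels)}
    for c in montage:
        if c not in index:
            raise HarmonizationError(f"required channel {c!r} absent from recording")
    data = recording.data[[index[c] for c in montage], :]

    if target_rate != recording.sampling_rate:
        from fractions import Fraction

        frac = Fraction(target_rate / recording.sampling_rate).limit_denominator(1000)
        data = sps.resample_poly(data, frac.numerator, frac.denominator, axis=-1)
    data = data - data.mean(axis=0, keepdims=True)
    return replace(
        recording, sampling_rate=float(target_rate), channels=montage, data=data
    )


def filter_line_noise(
    recording: ContinuousRecording, line_freq: float = 60.0, width: float = 2.0
) -> ContinuousRecording:
    """Suppress power-line interference with a zero-phase band-stop filter.

    The stop band is ``line_freq +- width`` Hz (4th-order Butterworth applied
    forward and backward), which attenuates the +-1 Hz neighbourhood of the
    line frequency by far more than 20 dB while leaving the 1–30 Hz passband
    essentially untouched.
    """
    nyq = recording.sampling_rate / 2.0
    if line_freq >= nyq:
        raise ValueError(f"line frequency {line_freq} Hz is at/above Nyquist {nyq} Hz")
    lo, hi = line_freq - width, min(line_freq + width, 0.99 * nyq)
    sos = sps.butter(4, [lo, hi], btype="bandstop", fs=recording.sampling_rate, output="sos")
    return replace(recording, data=sps.sosfiltfilt(sos, recording.data, axis=-1))


def bandpass(recording: ContinuousRecording, lo: float, hi: float) -> ContinuousRecording:
    """Zero-phase 4th-order Butterworth band-pass between ``lo`` and ``hi`` Hz."""
    nyq = recording.sampling_rate / 2.0
    if not (0.0 < lo < hi < nyq):
        raise ValueError(f"band [{lo}, {hi}] Hz invalid for Nyquist {nyq} Hz")
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=recording.sampling_rate, output="sos")
    return replace(recording, data=sps.sosfiltfilt(sos, recording.data, axis=-1))


def epoch(recording: ContinuousRecording, epoch_length: float = DEFAULT_EPOCH_LENGTH) -> EpochedRecording:
    """Cut the continuous record into fixed-length epochs (remainder discarded)."""
    n_per = int(round(epoch_length * recording.sampling_rate))
    if n_per < 1:
        raise ValueError("epoch_length too short for the sampling rate")
    n_epochs = recording.data.shape[1] // n_per
    if n_epochs == 0:
        raise QualityError("recording shorter than one epoch")
    data = recording.data[:, : n_epochs * n_per]
    data = data.reshape(len(recording.channels), n_epochs, n_per).transpose(1, 0, 2)
    return EpochedRecording(
        subject_id=recording.subject_id,
        site=recording.site,
        timepoint=recording.timepoint,
        sampling_rate=recording.sampling_rate,
        channels=list(recording.channels),
        data=data.copy(),
        epoch_length=epoch_length,
        kept_epoch_mask=np.ones(n_epochs, dtype=bool),
    )


def reject_artifacts(
    epoched: EpochedRecording,
    peak_threshold: float = DEFAULT_PEAK_THRESHOLD_UV,
    min_epochs: int = DEFAULT_MIN_EPOCHS,
) -> EpochedRecording:
    """Drop epochs whose absolute amplitude exceeds the threshold on any channel.

    ``kept_epoch_mask`` is updated against the original epoch grid, so the
    operation is idempotent.  Raises :class:`QualityError` if fewer than
    ``min_epochs`` epochs survive (subject flagged for exclusion).
    """
    if peak_threshold <= 0:
        raise ValueError("peak_threshold must be > 0")
    keep_local = np.abs(epoched.data).max(axis=(1, 2)) <= peak_threshold
    mask = epoched.kept_epoch_mask.copy()
    mask[np.flatnonzero(mask)] = keep_local
    kept = epoched.data[keep_local]
    if kept.shape[0] < min_epochs:
        raise QualityError(
            f"only {kept.shape[0]} epochs survive rejection (< {min_epochs}); "
            f"subject {epoched.subject_id} flagged for exclusion"
        )
    return replace(epoched, data=kept, kept_epoch_mask=mask)


def preprocess_recording(
    raw: ContinuousRecording,
    target_rate: float = DEFAULT_TARGET_RATE,
    target_montage: list[str] | None = None,
    line_freq: float = 60.0,
    band: tuple[float, float] = (1.0, 30.0),
    epoch_length: float = DEFAULT_EPOCH_LENGTH,
    peak_threshold: float = DEFAULT_PEAK_THRESHOLD_UV,
    min_epochs: int = DEFAULT_MIN_EPOCHS,
) -> EpochedRecording:
    """Full cleaning chain: harmonize -> line filter -> band-pass -> epoch -> reject."""
    rec = harmonize(raw, target_rate, target_montage)
    rec = filter_line_noise(rec, line_freq)
    rec = bandpass(rec, *band)
    return reject_artifacts(epoch(rec, epoch_length), peak_threshold, min_epochs)


# ---------------------------------------------------------------------------
# I/O


def read_raw(path, subject_id: str, site: str, timepoint: str) -> ContinuousRecording:
    """Read an EDF or BrainVision file into a ContinuousRecording (microvolts)."""
    import mne

    path = Path(path)
    if path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported raw format: {path.suffix}")
    return ContinuousRecording(
        subject_id=subject_id,
        site=site,
        timepoint=timepoint,
        sampling_rate=float(raw.info["sfreq"]),
        channels=list(raw.ch_names),
        data=raw.get_data() * 1e6,  # MNE returns volts
    )


def save_epoched(rec: EpochedRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("channels", data=np.array(rec.channels, dtype="S"))
        f.create_dataset("mask", data=rec.kept_epoch_mask)
        f.attrs["sampling_rate"] = rec.sampling_rate
        f.attrs["subject_id"] = rec.subject_id
        f.attrs["site"] = rec.site
        f.attrs["timepoint"] = rec.timepoint
        f.attrs["epoch_length"] = rec.epoch_length


def load_epoched(path) -> EpochedRecording:
    with h5py.File(path, "r") as f:
        return EpochedRecording(
            subject_id=str(f.attrs["subject_id"]),
            site=str(f.attrs["site"]),
            timepoint=str(f.attrs["timepoint"]),
            sampling_rate=float(f.attrs["sampling_rate"]),
            channels=[c.decode() for c in f["channels"][()]],
            data=f["data"][()],
            epoch_length=float(f.attrs["epoch_length"]),
            kept_epoch_mask=f["mask"][()],
        )


def save_continuous(rec: ContinuousRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("channels", data=np.array(rec.channels, dtype="S"))
        f.attrs["sampling_rate"] = rec.sampling_rate
        f.attrs["subject_id"] = rec.subject_id
        f.attrs["site"] = rec.site
        f.attrs["timepoint"] = rec.timepoint


def load_continuous(path) -> ContinuousRecording:
    with h5py.File(path, "r") as f:
        return ContinuousRecording(
            subject_id=str(f.attrs["subject_id"]),
            site=str(f.attrs["site"]),
            timepoint=str(f.attrs["timepoint"]),
            sampling_rate=float(f.attrs["sampling_rate"]),
            channels=[c.decode() for c in f["channels"][()]],
            data=f["data"][()],
        )
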