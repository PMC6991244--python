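import numpy as np
import pytest

from restpredict.preprocess import ContinuousRecording, EpochedRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_continuous(
    data: np.ndarray,
    sampling_rate: float = 250.0,
    channels: list[str] | None = None,
    **kwargs,
) -> ContinuousRecording:
    channels = channels or [f"ch{i}" for i in range(data.shape[0])]
    defaults = dict(subject_id="sub-0001", site="A", timepoint="baseline")
    defaults.update(kwargs)
    return ContinuousRecording(
        sampling_rate=sampling_rate, channels=channels, data=data, **defaults
    )


def make_epoched(
    data: np.ndarray,
    sampling_rate: float = 250.0,
    channels: list[str] | None = None,
    **kwargs,
) -> EpochedRecording:
    channels = channels or [f"ch{i}" for i in range(data.shape[1])]
    defaults = dict(subject_id="sub-0001", site="A", timepoint="baseline")
    defaults.update(kwargs)
    return EpochedRecording(
        sampling_rate=sampling_rate,
        channels=channels,
        data=data,
        epoch_length=data.shape[2] / sampling_rate,
        kept_epoch_mask=np.ones(data.shape[0], dtype=bool),
        **defaults,
    )


@pytest.fixture
def sine_epochs():
    """30 x 4ch x 500-sample epochs of a pure 10.5 Hz unit sinusoid at 250 Hz."""
    fs = 250.0
    t = np.arange(30 * 500) / fs
    x = np.sin(2 * np.pi * 10.5 * t)
    data = np.tile(x.reshape(30, 1, 500), (1, 4, 1))
    return make_epoched(data, fs)
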