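import numpy as np
import pytest

from eegsnet.signal_io import Recording, SleepEpoch, Stage, StageLabel
from eegsnet.spectrogram import epoch_to_image
from eegsnet.synthetic_data import generate_dataset


def epoch_of(samples: np.ndarray, rate: float, stage: Stage = Stage.N2) -> SleepEpoch:
    return SleepEpoch(
        subject_id="fix",
        epoch_index=0,
        samples=samples,
        label=StageLabel(stage, stage.name),
        sample_rate=rate,
    )


def tone_epoch(freq_hz: float, rate: float = 100.0, amp: float = 1.0) -> SleepEpoch:
    t = np.arange(int(30 * rate)) / rate
    return epoch_of(amp * np.sin(2 * np.pi * freq_hz * t), rate)


@pytest.fixture(scope="session")
def tiny_dataset():
    """6 synthetic subjects × 40 epochs as (images, labels) per subject."""
    subs = generate_dataset(6, 40, rate=100.0, seed=7)
    data = {}
    for s in subs:
        eps = s.epochs()
        imgs = np.stack([epoch_to_image(e).pixels for e in eps]).astype(np.float32)
        labs = np.array([e.label.value.value for e in eps], dtype=np.int64)
        data[s.subject_id] = (imgs, labs)
    return data


@pytest.fixture(scope="session")
def synthetic_subjects():
    return generate_dataset(3, 20, rate=100.0, seed=11)
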