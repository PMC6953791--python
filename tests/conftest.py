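import numpy as np
import pytest

from falarm import (
    AlarmType,
    ChannelRole,
    Label,
    ModalConfig,
    SyntheticSpec,
    WaveformRecord,
    generate_dataset,
)


@pytest.fixture(scope="session")
def tiny_modal_config() -> ModalConfig:
    """A miniature architecture for fast exact checks (float64 for gradients)."""
    return ModalConfig(
        n=40,
        conv1_filters=3,
        conv2_filters=4,
        n_slices=2,
        attention_width=3,
        lstm_size=5,
        fc_size=6,
        dtype="float64",
    )


@pytest.fixture(scope="session")
def small_dataset():
    """20 synthetic records, balanced, all five alarm types."""
    return generate_dataset(SyntheticSpec(n_records=20, seed=11))


def make_record(x: np.ndarray, fs: float = 250.0, onset: int | None = None,
                role: ChannelRole = ChannelRole.ECG_II) -> WaveformRecord:
    """Single-channel record wrapper for preprocessing tests."""
    return WaveformRecord(
        record_id="rec",
        fs=fs,
        channels={role: np.asarray(x, dtype=float)},
        alarm_type=AlarmType.VTA,
        label=Label.UNKNOWN,
        onset_index=onset if onset is not None else len(x),
    )
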