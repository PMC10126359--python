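import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nirsmci.dataio import AcquisitionSpec, EventTable, RawRecording

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def tiny_recording() -> RawRecording:
    """Minimal 2-channel, 1 s recording with integer-valued intensities."""
    acq = AcquisitionSpec(
        sampling_rate=10.0,
        n_channels=2,
        channel_region_map={1: "left_pfc", 2: "right_pfc"},
    )
    events = EventTable(
        pd.DataFrame(
            {
                "block": [1],
                "encoding_onset_s": [0.1],
                "encoding_duration_s": [0.2],
                "recall_onset_s": [0.4],
                "rest_onset_s": [0.7],
            }
        )
    )
    rng = np.random.default_rng(7)
    intensity = rng.integers(1, 100, size=(2, 2, 10)).astype(float)
    return RawRecording(
        subject_id="s01",
        group="healthy",
        acquisition=acq,
        events=events,
        intensity=intensity,
        moca_k=27.0,
        vdst_score=14.0,
        demographics={"age": 70.0, "sex": "female", "education": 9.0},
    )
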