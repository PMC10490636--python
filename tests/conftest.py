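import numpy as np
import pandas as pd
import pytest

from insole_weight import schema
from insole_weight.moticon_io import (
    RecordingKey,
    SensorRecording,
    load_ground_truth,
    scan_dataset,
    select_participants,
)
from insole_weight.synthetic_insole import CohortSpec, generate_cohort


def make_recording(values: dict | None = None, n: int = 10,
                   key: RecordingKey | None = None, rate: float = 50.0,
                   participant_id: str | None = None) -> SensorRecording:
    """Minimal valid recording: all channels constant unless overridden."""
    data = pd.DataFrame(0.0, index=range(n), columns=list(schema.COLUMNS))
    data[schema.TIME_COLUMN] = np.arange(n) / rate
    for col, val in (values or {}).items():
        data[col] = val
    return SensorRecording(
        key=key or RecordingKey(0, "standing", 1),
        data=data,
        sampling_rate=rate,
        participant_id=participant_id,
    )


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A tiny on-disk cohort (1 balanced + 1 unbalanced, short recordings)
    shared by I/O and pipeline tests."""
    root = tmp_path_factory.mktemp("small_cohort")
    base = CohortSpec(duration_per_weight=6.0, weight_class=(0, 2, 5),
                      n_iterations=2)
    manifest = generate_cohort(1, 1, base, root, seed=11)
    return root, manifest


@pytest.fixture(scope="session")
def small_cohort_data(small_cohort):
    root, manifest = small_cohort
    inventory = scan_dataset(root)
    ground_truth = load_ground_truth(root / "ground_truth.csv")
    eligible = select_participants(inventory)
    return inventory, ground_truth, eligible
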