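import numpy as np
import pandas as pd
import pytest

from contextdrift.datatypes import BoldRun, ClipSchedule, DurationReport
from contextdrift.synthgen import RoiSpec, SynthConfig, generate_dataset


def small_config(seed: int = 0, **overrides) -> SynthConfig:
    """A fast, fully featured configuration for unit tests."""
    defaults = dict(
        seed=seed,
        n_participants=4,
        n_trs=400,
        n_intervals_2min=8,
        n_intervals_6min=4,
        roi_specs=(
            RoiSpec("drift_roi", 30, 1.0, 1.0, "grey"),
            RoiSpec("null_roi", 30, 0.0, 1.0, "grey"),
            RoiSpec("wm", 20, 0.0, 1.0, "white"),
            RoiSpec("csf", 15, 0.0, 1.0, "csf"),
            RoiSpec("ventricle", 12, 0.0, 0.5, "csf"),
        ),
    )
    defaults.update(overrides)
    return SynthConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config(seed=11))


@pytest.fixture()
def simple_schedule():
    """Hand-built schedule: 4 intervals, two true gaps, known positions."""
    clips = pd.DataFrame(
        {
            "clip_id": [f"c{i}" for i in range(8)],
            "onset_s": [0.0, 120.0, 60.0, 180.0, 150.0, 510.0, 300.0, 420.0],
            "duration_s": [6.0] * 8,
        }
    )
    intervals = pd.DataFrame(
        {
            "interval_id": ["i0", "i1", "i2", "i3"],
            "clip_a": ["c0", "c2", "c4", "c6"],
            "clip_b": ["c1", "c3", "c5", "c7"],
            "true_gap_s": [120.0, 120.0, 360.0, 120.0],
            "position_s": [63.0, 123.0, 333.0, 363.0],
        }
    )
    return ClipSchedule(clips=clips, intervals=intervals)


def make_report(pid, interval_ids, estimates, clip_conf=None, group="original"):
    return DurationReport(
        participant_id=pid,
        estimates=pd.Series(np.asarray(estimates, dtype=float),
                            index=list(interval_ids)),
        clip_confidence=pd.Series(clip_conf or {}, dtype=float),
        group=group,
    )


def make_run(data, tr=1.5, pid="sub-00", roi="roi"):
    data = np.asarray(data, dtype=float)
    n_vox = data.shape[0]
    coords = np.column_stack(
        [np.arange(n_vox), np.zeros(n_vox, int), np.zeros(n_vox, int)]
    )
    return BoldRun(
        participant_id=pid,
        data=data,
        tr=tr,
        coords=coords,
        compartments=np.array(["grey"] * n_vox, dtype=object),
        roi_labels=np.array([roi] * n_vox, dtype=object),
    )
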