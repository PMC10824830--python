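import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dyadsync import io as mio

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240116)


def make_table(frames, markers, coords=None, fps=120.0, rng=None):
    """Long-format MarkerFrameTable from a frame range and marker ids.

    ``coords[marker]`` is an (n, 3) array; defaults to a random walk.
    """
    rng = rng or np.random.default_rng(0)
    rows = []
    for m in markers:
        xyz = coords[m] if coords else rng.normal(0, 1, (len(frames), 3)).cumsum(axis=0)
        for i, f in enumerate(frames):
            rows.append({"frame": f, "marker": m,
                         "x_mm": xyz[i, 0], "y_mm": xyz[i, 1], "z_mm": xyz[i, 2]})
    return mio.MarkerFrameTable(pd.DataFrame(rows), fps=fps)


def make_recording(child_path, storyteller_path, fps=120.0):
    """Minimal LabeledRecording: one back marker per interactant."""
    n = len(child_path)
    assert len(storyteller_path) == n
    return mio.LabeledRecording(
        {
            "child": {"c0": np.asarray(child_path, dtype=float)},
            "storyteller": {"s0": np.asarray(storyteller_path, dtype=float)},
        },
        frames=np.arange(n),
        fps=fps,
    )


@pytest.fixture
def simple_labels():
    entries = {}
    for who in ("child", "storyteller"):
        for i, region in enumerate(
            ["upper_back_left", "upper_back_right", "lower_back_left", "lower_back_right"]
        ):
            entries[f"{who[0]}{i}"] = (who, region)
    return mio.make_labeling_map(entries)
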