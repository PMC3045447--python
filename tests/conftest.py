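"""Shared fixtures.

``mini_run`` is a down-scaled but complete pipeline execution (64³ phantom,
60 projections) shared by the segmentation, pipeline and determinism tests;
``full_run`` is the default study phantom at full scale (256³, 240
projections) and is computed once per session for the end-to-end recovery
checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from xpcilung.pipeline import run_all

MINI_OVERRIDES = {
    "phantom": {
        "extent_um": [640.0, 640.0, 640.0],
        "pitch_um": 8.0,
        "body_radius_um": 300.0,
        "tree": {
            "depth": 3,
            "root_radius_um": 50.0,
            "radius_ratio": 0.85,
            "root_length_um": 125.0,
            "length_ratio": 0.8,
            "root_start_um": [70.0, 320.0, 320.0],
        },
        "alveoli": {"count": 4, "max_tries_per_alveolus": 2000},
        "ribs": {"count": 1, "tube_radius_um": 50.0, "arc_radius_um": 220.0,
                 "arc_span_deg": 110.0},
    },
    "beam": {"n_angles": 90},
}

MINI_SEED = 7
FULL_SEED = 1


@pytest.fixture(scope="session")
def mini_run():
    return run_all(MINI_OVERRIDES, seed=MINI_SEED)


@pytest.fixture(scope="session")
def full_run():
    return run_all(seed=FULL_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def match_measured_to_truth(result):
    """Pair each planted alveolus with the measured component covering its
    center (searching one voxel around); returns a list of
    (truth, stats row or None)."""
    ct = result["ct"]
    phantom = result["phantom"]
    stats = result["stats"]
    labels = result["alveoli"].labels
    off = result["projections"].meta["detector_offset_um"]
    pitch = ct.pitch_um
    nz, ny, nx = ct.values.shape
    ext = phantom.spec.extent_um
    pairs = []
    for truth in phantom.alveoli:
        c = truth.center_um
        i = (int(round((c[0] - off[0]) / pitch - 0.5)),
             int(round((c[1] - ext[1] / 2) / pitch + (ny - 1) / 2)),
             int(round((c[2] - ext[2] / 2) / pitch + (nx - 1) / 2)))
        lab = labels[i]
        if lab == 0:
            window = labels[max(i[0] - 1, 0):i[0] + 2,
                            max(i[1] - 1, 0):i[1] + 2,
                            max(i[2] - 1, 0):i[2] + 2]
            lab = window.max()
        row = None
        if lab > 0:
            hit = stats[stats["id"] == lab]
            if len(hit):
                row = hit.iloc[0]
        pairs.append((truth, row))
    return pairs
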