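import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from digikit.geometry import RigidTransform, random_rotation
from digikit.simulator import ScenarioConfig, generate_layout


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_random_transform(rng, scale_mm: float = 100.0) -> RigidTransform:
    return RigidTransform(random_rotation(rng), rng.uniform(-scale_mm, scale_mm, 3))


@pytest.fixture
def random_transform(rng):
    return make_random_transform(rng)


def small_scenario(seed: int = 0, n_electrodes: int = 32, **kw) -> ScenarioConfig:
    """Downsized scenario for fast tests (spacing target widened to match)."""
    kw.setdefault("neighbor_spacing_mm", (10.0, 80.0))
    return ScenarioConfig(seed=seed, n_electrodes=n_electrodes, **kw)


def drift_motion(drift_mm: float, duration_s: float = 60.0, rot_deg: float = 2.0):
    """Piecewise-linear head drift starting at identity."""
    return [
        {"t": 0.0, "translation_mm": [0.0, 0.0, 0.0]},
        {
            "t": duration_s,
            "translation_mm": [drift_mm, 0.0, 0.0],
            "rotvec_deg": [0.0, 0.0, rot_deg],
        },
    ]


@pytest.fixture
def default_truth():
    return generate_layout(ScenarioConfig(seed=11))
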