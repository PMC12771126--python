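import math

import numpy as np
import pytest
from hypothesis import settings

from confunnel import Conformer

settings.register_profile("det", derandomize=True)
settings.load_profile("det")


def hexagon(radius: float, z: float = 0.0) -> np.ndarray:
    ang = np.arange(6) * math.pi / 3.0
    return np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang), np.full(6, z)]
    )


@pytest.fixture
def benzene_carbons() -> Conformer:
    """Idealized planar C6 ring (hydrogens omitted; ring logic only needs C)."""
    return Conformer("benzene", "fix", ("C",) * 6, hexagon(1.39))


@pytest.fixture
def cyclohexane_chair() -> Conformer:
    """Idealized chair C6 ring: planar filter must reject it."""
    coords = hexagon(math.sqrt(1.54**2 - 0.25))
    coords[:, 2] = 0.25 * np.array([1, -1, 1, -1, 1, -1])
    return Conformer("chair", "fix", ("C",) * 6, coords)


@pytest.fixture
def water_like() -> Conformer:
    """Bent 3-atom geometry (O at apex, 0.96 Å bonds, 104.5° angle)."""
    theta = math.radians(104.5 / 2)
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [0.96 * math.sin(theta), 0.0, -0.96 * math.cos(theta)],
            [-0.96 * math.sin(theta), 0.0, -0.96 * math.cos(theta)],
        ]
    )
    return Conformer("w", "fix", ("O", "H", "H"), coords)


@pytest.fixture
def nitrogen_diatomic() -> Conformer:
    return Conformer(
        "n2", "fix", ("N", "N"), np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 1.09768]])
    )


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
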