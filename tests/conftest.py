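import numpy as np
import pytest

from phasetex import PhysicsConfig, RefractiveMap, Stage


@pytest.fixture(scope="session")
def physics() -> PhysicsConfig:
    """Default beamline: 13 keV, 85 cm propagation, 9 um pixels."""
    return PhysicsConfig()


def make_map(delta: np.ndarray, beta: np.ndarray, pixel_size: float = 9e-6,
             stage: Stage = Stage.NORMAL, mask: np.ndarray | None = None) -> RefractiveMap:
    """Assemble a RefractiveMap from raw grids (mask defaults to all-true)."""
    if mask is None:
        mask = np.ones(delta.shape, dtype=bool)
    return RefractiveMap(delta_grid=np.asarray(delta, dtype=float),
                         beta_grid=np.asarray(beta, dtype=float),
                         pixel_size=pixel_size, stage_label=stage, wall_mask=mask)


@pytest.fixture
def vacuum_map() -> RefractiveMap:
    """An empty specimen: delta = beta = 0 on a 64x64 grid."""
    z = np.zeros((64, 64))
    return make_map(z, z.copy())
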