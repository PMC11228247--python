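import numpy as np
import pytest

from isletnet import CellRecord, IsletMap, RimPolygon
from isletnet.simulate import IsletSimParams, generate_islet


@pytest.fixture
def square_rim() -> RimPolygon:
    """Axis-aligned square with corners (±10, ±10)."""
    return RimPolygon(np.array([(-10, -10), (10, -10), (10, 10), (-10, 10)], float))


@pytest.fixture
def circle_rim() -> RimPolygon:
    """Fine polygonal approximation of a circle of radius 50 μm."""
    t = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    return RimPolygon(np.c_[50 * np.cos(t), 50 * np.sin(t)])


@pytest.fixture
def islet_factory():
    """Synthetic islet generator with overridable parameters."""

    def make(seed: int = 0, **kwargs) -> IsletMap:
        params = IsletSimParams(rng_seed=seed, **kwargs)
        return generate_islet(params, islet_id=f"islet_s{seed}")

    return make


@pytest.fixture
def default_islet(islet_factory) -> IsletMap:
    return islet_factory(seed=42, target_t_beta_ratio=0.4)


def manual_islet(rim: RimPolygon, cells, islet_id="manual") -> IsletMap:
    """Hand-placed islet from (cell_id, type, x, y) tuples."""
    return IsletMap(
        islet_id=islet_id,
        mouse_id="m1",
        rim=rim,
        cells=[CellRecord(*c) for c in cells],
    )
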