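import numpy as np
import pytest

from activewet.fields import RadialProfile, VectorField
from activewet.params import ModelParams, TractionFitParams


@pytest.fixture
def annulus_params() -> ModelParams:
    """Reference annular parameter set used throughout the suite."""
    return ModelParams(A=2e-3, B=0.05, Lc=40.0, R=200.0, R1=60.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def profile_from_arrays(r, y, sem=None) -> RadialProfile:
    r = np.asarray(r, dtype=float)
    y = np.asarray(y, dtype=float)
    return RadialProfile(
        r_centers=r, value=y,
        sem=np.zeros_like(r) if sem is None else np.asarray(sem, dtype=float),
        n=np.ones(r.size, dtype=int), bin_width=float(r[1] - r[0]),
    )


def uniform_field(shape=(8, 8), u0=3.0, v0=4.0, spacing=10.0) -> VectorField:
    ny, nx = shape
    return VectorField(
        grid_x=np.arange(nx) * spacing, grid_y=np.arange(ny) * spacing,
        u=np.full(shape, u0), v=np.full(shape, v0),
        mask=np.ones(shape, dtype=bool),
    )
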