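import numpy as np
import pytest

from strokedti.image_io import ImageGrid, default_gradient_table
from strokedti.synthetic_data import PhantomSpec, make_phantom
from strokedti.tensor_fit import TensorVolume


@pytest.fixture(scope="session")
def table():
    return default_gradient_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless intact phantom on a small grid, shared across tests."""
    spec = PhantomSpec(grid=ImageGrid((48, 48, 2)), snr=None)
    labels, truth_tv, truth_md = make_phantom(spec)
    return spec, labels, truth_tv, truth_md


def random_spd_tensors(rng, n, lam_max=3e-3, lam_min=1e-4):
    """Random physical (symmetric positive-definite) tensors as (n, 3, 3)."""
    lam = rng.uniform(lam_min, lam_max, (n, 3))
    q, _ = np.linalg.qr(rng.normal(size=(n, 3, 3)))
    return np.einsum("nij,nj,nkj->nik", q, lam, q)


def uniform_isotropic_volume(shape, d=3e-4, s0=1000.0):
    """TensorVolume with one isotropic tensor everywhere (test phantom)."""
    grid = ImageGrid(shape)
    elems = np.zeros(grid.shape + (6,))
    elems[..., :3] = d
    return TensorVolume(
        grid=grid,
        d=elems,
        ln_s0=np.full(grid.shape, np.log(s0)),
        residual_rms=np.zeros(grid.shape),
        mask=np.ones(grid.shape, dtype=bool),
    )
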