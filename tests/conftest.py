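import numpy as np
import pytest

from fodfbias.odf_core import DirectionSet, FODFField, default_sphere
from fodfbias.tracking import TissueMaps


@pytest.fixture(scope="session")
def sphere():
    return default_sphere()


@pytest.fixture(scope="session")
def toy_dirs():
    """Six antipodal pairs: the three axes plus three axial diagonals."""
    half = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0],
            [0.0, 0.0, 1.0],
            [1.0, 1.0, 0.0],
            [1.0, 0.0, 1.0],
            [0.0, 1.0, 1.0],
        ]
    )
    half /= np.linalg.norm(half, axis=1, keepdims=True)
    return DirectionSet(np.concatenate([half, -half]), name="toy12")


def make_slab(direction_index, dirs, nx=12, ny=5, nz=5):
    """A WM slab along x with GM caps at both x ends and CSF on y/z walls.

    All fODF mass sits on one antipodal direction pair of ``dirs``.
    """
    n = dirs.count
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    gm = (ii == 0) | (ii == nx - 1)
    csf = ((jj == 0) | (jj == ny - 1) | (kk == 0) | (kk == nz - 1)) & ~gm
    wm = ~gm & ~csf
    dens = np.zeros((nx, ny, nz, n), dtype=np.float64)
    v = dirs.vectors[direction_index]
    anti = int(np.argmin(dirs.vectors @ v))
    dens[wm, direction_index] = 1.0
    dens[wm, anti] = 1.0
    affine = np.eye(4)
    field = FODFField(densities=dens, affine=affine, directions=dirs)
    tissue = TissueMaps(
        gm=gm.astype(float), wm=wm.astype(float), csf=csf.astype(float), affine=affine
    )
    return field, tissue, wm
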