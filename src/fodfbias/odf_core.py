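"""Direction-set geometry, the orientation-angle statistic phi, and fODF handling.

An fODF (fiber orientation distribution function) is a per-voxel density over
orientations on the sphere; its peaks mark putative axonal fiber directions.
Orientation is a *line*, not a ray, so every direction set used here is
antipodally symmetric: for each unit vector ``v`` the set also contains ``-v``.

World axes follow the RAS convention: +x right (medial-lateral axis),
+y anterior (anterior-posterior axis), +z superior.

The orientation angle ``phi`` of a direction ``v`` is defined in the axial
(x-y) plane: project ``v`` to ``d' = (x, y)``; ``phi`` is the signed complement
of the acute angle between ``d'`` and the M-L (x) axis, so that

* ``phi = 0``    when ``d'`` lies on the A-P axis (either half),
* ``phi = -90``  when ``d'`` lies on the right half of the M-L axis,
* ``phi = +90``  when ``d'`` lies on the left half of the M-L axis.

Directions with (near-)zero axial projection have no defined ``phi`` and are
marked NaN with an explicit ``defined`` flag; they are never silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import DegenerateVoxelError, ParameterError

__all__ = [
    "DirectionSet",
    "OrientationAngles",
    "FODFField",
    "build_default_sphere",
    "default_sphere",
    "orientation_angle",
    "angles_for_set",
    "fodf_to_pmf",
    "ml_mass_fraction",
]

#: tolerance below which an axial projection counts as zero (relative to |v|)
AXIAL_TOL = 1e-8

_UNIT_TOL = 1e-9

_DEFAULT_SPHERE_FILE = "sphere362_v1.tsv"
_default_sphere_cache: "DirectionSet | None" = None


@dataclass(frozen=True)
class DirectionSet:
    """An antipodally symmetric set of unit orientation vectors.

    All subjects of a cohort must index their fODF direction axis with the
    *same* DirectionSet; cross-subject reweighting is per direction index.
    """

    vectors: np.ndarray  # (n, 3) float64
    name: str = "custom"

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vectors, dtype=np.float64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise ParameterError("DirectionSet vectors must have shape (n, 3)")
        object.__setattr__(self, "vectors", v)
        norms = np.linalg.norm(v, axis=1)
        if not np.all(np.abs(norms - 1.0) <= 1e-6):
            raise ParameterError("DirectionSet vectors must be unit length")
        if v.shape[0] % 2:
            raise ParameterError("antipodal symmetry requires an even count")
        # antipodal closure: every -v must be present (within tolerance)
        d = v @ v.T
        if not np.all(d.min(axis=1) <= -1.0 + 1e-9):
            raise ParameterError("DirectionSet is not antipodally closed")

    @property
    def count(self) -> int:
        return int(self.vectors.shape[0])

    def __len__(self) -> int:
        return self.count


@dataclass(frozen=True)
class OrientationAngles:
    """Per-direction orientation angles for a DirectionSet.

    ``phi`` is in degrees within [-90, 90]; entries whose axial projection is
    (near-)zero are NaN and flagged False in ``defined``.
    """

    phi: np.ndarray             # (n,) float64, NaN where undefined
    defined: np.ndarray         # (n,) bool
    axial_projection: np.ndarray  # (n, 2) float64

    @property
    def n_undefined(self) -> int:
        return int((~self.defined).sum())


@dataclass
class FODFField:
    """A voxel grid of fODF density values over a shared DirectionSet.

    ``densities`` is indexed (i, j, k, direction) and must be nonnegative and
    finite; the 4x4 ``affine`` maps voxel indices (centers at integers) to
    world mm coordinates.
    """

    densities: np.ndarray
    affine: np.ndarray
    directions: DirectionSet
    name: str = ""

    def __post_init__(self):
        d = np.asarray(self.densities)
        if d.ndim != 4:
            raise ParameterError("FODFField densities must be 4-D (i, j, k, dir)")
        if d.shape[3] != self.directions.count:
            raise ParameterError(
                f"direction axis length {d.shape[3]} != DirectionSet count "
                f"{self.directions.count}"
            )
        if not np.all(np.isfinite(d)):
            raise ParameterError("FODFField densities must be finite")
        self.densities = d
        self.affine = np.asarray(self.affine, dtype=np.float64).reshape(4, 4)

    @property
    def grid_shape(self) -> tuple:
        return self.densities.shape[:3]


def build_default_sphere(
    n_pairs: int = 181,
    optimization_seed: int = 0,
    n_iter: int = 400,
) -> DirectionSet:
    """Place ``n_pairs`` antipodal direction pairs by electrostatic repulsion.

    Antipodal point pairs are initialized uniformly at random (seeded) and
    iteratively pushed apart by Coulomb-type forces between every point and
    every other point *and its antipode*, maximizing the minimum pairwise
    angular separation.  The procedure is deterministic: a fixed seed yields a
    bit-identical direction set.  The default (181 pairs) yields the 362
    directions all cohort fODFs are sampled on.
    """
    if n_pairs < 6:
        raise ParameterError("n_pairs must be at least 6")
    rng = np.random.default_rng(optimization_seed)
    p = rng.normal(size=(n_pairs, 3))
    p /= np.linalg.norm(p, axis=1, keepdims=True)

    lr = 0.05
    for it in range(n_iter):
        # force on p_i from p_j and from -p_j, inverse-square in chord length
        diff_pos = p[:, None, :] - p[None, :, :]          # p_i - p_j
        diff_neg = p[:, None, :] + p[None, :, :]          # p_i - (-p_j)
        d_pos = np.linalg.norm(diff_pos, axis=2)
        d_neg = np.linalg.norm(diff_neg, axis=2)
        np.fill_diagonal(d_pos, np.inf)
        np.fill_diagonal(d_neg, np.inf)  # self-antipode force is radial anyway
        f = (diff_pos / d_pos[..., None] ** 3).sum(axis=1)
        f += (diff_neg / d_neg[..., None] ** 3).sum(axis=1)
        # project onto the tangent plane and take a small step
        f -= (f * p).sum(axis=1, keepdims=True) * p
        step = lr * (1.0 - it / n_iter)
        p = p + step * f / max(n_pairs, 1)
        p /= np.linalg.norm(p, axis=1, keepdims=True)

    vectors = np.concatenate([p, -p], axis=0)
    return DirectionSet(vectors, name=f"repulsion{2 * n_pairs}_seed{optimization_seed}")


def default_sphere() -> DirectionSet:
    """The package's versioned 362-direction sphere.

    Loaded from a fixture shipped with the package so that every subject and
    every run shares bit-identical directions (a requirement for per-direction
    cross-subject statistics).  The fixture was produced by
    ``build_default_sphere(181, optimization_seed=0)``.
    """
    global _default_sphere_cache
    if _default_sphere_cache is None:
        ref = resources.files("fodfbias.data").joinpath(_DEFAULT_SPHERE_FILE)
        with ref.open("r") as fh:
            vecs = np.loadtxt(fh, delimiter="\t", skiprows=1)
        _default_sphere_cache = DirectionSet(vecs, name="sphere362_v1")
    return _default_sphere_cache


def orientation_angle(v, tol: float = AXIAL_TOL) -> float:
    """Orientation angle phi (degrees) of a single 3-vector.

    Returns NaN when the axial projection is zero within ``tol`` relative to
    ``|v|`` (the angle is undefined for superior-inferior directions).
    Raises ParameterError for the zero vector.
    """
    v = np.asarray(v, dtype=np.float64)
    if v.shape != (3,):
        raise ParameterError("orientation_angle expects a single 3-vector")
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise ParameterError("orientation angle of the zero vector is undefined")
    x, y = float(v[0]), float(v[1])
    r = math.hypot(x, y)
    if r <= tol * n:
        return math.nan
    if x == 0.0:
        return 0.0
    # |phi| = 90 deg minus the acute angle between d' and the x axis;
    # atan2 keeps this well conditioned near both axes
    phi = math.degrees(math.atan2(abs(x), abs(y)))
    return -phi if x > 0.0 else phi


def angles_for_set(ds: DirectionSet, tol: float = AXIAL_TOL) -> OrientationAngles:
    """Vectorized phi over a DirectionSet; undefined entries flagged, kept."""
    v = ds.vectors
    x, y = v[:, 0], v[:, 1]
    r = np.hypot(x, y)
    norms = np.linalg.norm(v, axis=1)
    defined = r > tol * norms
    mag = np.degrees(np.arctan2(np.abs(x), np.abs(y)))
    phi = np.where(x > 0, -mag, np.where(x < 0, mag, 0.0))
    phi = np.where(defined, phi, np.nan)
    return OrientationAngles(phi=phi, defined=defined, axial_projection=v[:, :2].copy())


def fodf_to_pmf(f: FODFField, voxel) -> np.ndarray:
    """Per-direction sampling probabilities for one voxel.

    Negative densities are floored to zero and the vector is normalized to
    unit sum.  An all-zero (or all-negative) voxel raises
    DegenerateVoxelError — the tracker treats that as a termination.
    """
    i, j, k = (int(c) for c in voxel)
    shape = f.grid_shape
    if not (0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]):
        raise ParameterError(f"voxel {(i, j, k)} outside grid {shape}")
    vec = np.clip(np.asarray(f.densities[i, j, k], dtype=np.float64), 0.0, None)
    s = vec.sum()
    if s <= 0.0:
        raise DegenerateVoxelError(f"voxel {(i, j, k)} has no positive density")
    return vec / s


def ml_mass_fraction(
    densities: np.ndarray,
    angles: OrientationAngles,
    mask: np.ndarray,
    phi_min_deg: float = 81.0,
) -> float:
    """Fraction of fODF mass in near-medial-lateral directions over a mask.

    Sums density over all mask voxels and directions with ``|phi| > phi_min``
    and divides by the total mass over all directions.  The default threshold
    (81 degrees) corresponds to the outermost two bins of the 20-bin phi
    histogram.  Scale-free: invariant to any global rescaling of the field.
    """
    d = np.asarray(densities, dtype=np.float64)
    sel = d[np.asarray(mask, dtype=bool)]  # (n_voxels, n_dirs)
    with np.errstate(invalid="ignore"):
        ml_dirs = np.abs(angles.phi) > phi_min_deg
    ml_dirs = ml_dirs & angles.defined
    total = sel.sum()
    if total <= 0:
        raise ParameterError("mask contains no fODF mass")
    return float(sel[:, ml_dirs].sum() / total)
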