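"""Synthetic multi-subject crossing-fiber phantom.

Emulates the deep white-matter scenario that motivates the correction: a
dominant anterior-posterior (A-P) bundle whose strength varies across
subjects, a weak medial-lateral (M-L) bundle that is *consistent* across
subjects, and directional noise that varies across subjects.  Because the
M-L signal is consistent, its cross-subject standard deviation is low, and
variance reweighting can recover it; because the A-P amplitude and the noise
vary, their directions are suppressed.

Geometry (all defaults, 24 x 24 x 12 voxels of 1 mm, RAS axes):

* gray-matter walls at the two M-L ends of the grid (x = 0 medial,
  x = max lateral) — seed side and target side;
* a CSF shell on the remaining boundary faces, so streamlines that wander
  along A-P or S-I are discarded rather than tracked forever;
* white matter everywhere inside;
* an M-L corridor — a 4 x 4-voxel column of WM connecting the medial wall to
  the lateral wall — where the weak M-L kernel lives.

Per WM voxel the fODF density over the shared DirectionSet is

    density(d) = a_AP,s * K(d; y_hat, kappa)                (dominant bundle)
               + a_ML * w(v) * K(d; x_hat, kappa)           (consistent bundle)
               + sum_j amp_j,s * K(d; axis_j,s, kappa)      (spurious peaks)
               + eps(v, d)                                  (directional noise)

with K an antipodally symmetric Watson-type kernel
``K(d; mu, kappa) = exp(kappa * ((d . mu)^2 - 1))`` (peak value 1), ``w(v)``
the corridor indicator, ``amp_j,s`` and ``axis_j,s`` subject-specific random
spurious-peak kernels, and ``eps`` zero-truncated Gaussian noise
(``max(N(0, tau^2), 0)``, keeping densities nonnegative without
renormalization).  The dominant amplitude is lognormal across subjects,
``a_AP,s = a_AP * exp(eta_s)`` with ``eta_s ~ N(0, ap_amp_cv^2)``: bundle
strength genuinely differs between individuals, and this across-subject
variability of the dominant peak is what lets the reweighting demote it
relative to the consistent M-L signal.

All randomness derives from ``(master_seed, subject_index)``, so cohorts are
pure functions of their parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ParameterError
from .odf_core import DirectionSet, FODFField, default_sphere
from .reweight import CohortFODF
from .tracking import TissueMaps

__all__ = [
    "PhantomParams",
    "PhantomBundle",
    "PhantomCohort",
    "watson_kernel",
    "generate_subject",
    "generate_cohort",
]


@dataclass(frozen=True)
class PhantomParams:
    """Generator parameters; the defaults define the study conditions."""

    grid_shape: tuple = (24, 24, 12)
    voxel_size_mm: float = 1.0
    a_ap: float = 1.0            # dominant A-P kernel amplitude (nominal)
    a_ml: float = 0.15           # consistent M-L kernel amplitude
    kappa: float = 20.0          # Watson concentration of all kernels
    noise_sd: float = 0.15       # tau, per-direction additive noise scale
    n_noise_kernels: int = 3     # spurious random-direction kernels per subject
    noise_kernel_amp_max: float = 0.3
    ap_amp_cv: float = 0.3       # across-subject lognormal spread of a_AP
    n_subjects: int = 20
    master_seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(g < 8 for g in self.grid_shape[:2]) or self.grid_shape[2] < 6:
            raise ParameterError("grid_shape too small for the phantom geometry")
        if self.a_ap < 0 or self.a_ml < 0:
            raise ParameterError("kernel amplitudes must be nonnegative")
        if self.kappa <= 0:
            raise ParameterError("kappa must be positive")
        if self.noise_sd < 0 or self.ap_amp_cv < 0:
            raise ParameterError("noise scales must be nonnegative")
        if self.n_subjects < 2:
            raise ParameterError("n_subjects must be at least 2")
        if self.n_noise_kernels < 0:
            raise ParameterError("n_noise_kernels must be nonnegative")


@dataclass
class PhantomBundle:
    """One subject's phantom: fODF field, tissue maps, masks, and truth."""

    fodf: FODFField
    tissue: TissueMaps
    masks: dict           # seed_roi, target_lateral, target_path, corridor, wm
    truth: np.ndarray     # noiseless density field (shared across subjects)
    subject_id: str = ""


@dataclass
class PhantomCohort:
    """A full cohort on a shared grid with shared tissue maps and masks."""

    cohort: CohortFODF
    tissue: TissueMaps
    masks: dict
    truth: np.ndarray
    params: PhantomParams


def watson_kernel(dirs: np.ndarray, axis, kappa: float) -> np.ndarray:
    """Antipodally symmetric orientation kernel with peak value 1."""
    axis = np.asarray(axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    t = np.asarray(dirs, dtype=np.float64) @ axis
    return np.exp(kappa * (t**2 - 1.0))


def _geometry(params: PhantomParams):
    """Tissue maps, masks, and the shared noiseless truth field support."""
    nx, ny, nz = params.grid_shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")

    gm = (ii == 0) | (ii == nx - 1)
    csf = ((jj == 0) | (jj == ny - 1) | (kk == 0) | (kk == nz - 1)) & ~gm
    wm = ~gm & ~csf

    cy, cz = ny // 2, nz // 2
    hw = 3  # corridor half-width in voxels
    corridor_yz = (
        (jj >= cy - hw) & (jj < cy + hw) & (kk >= cz - hw) & (kk < cz + hw)
    )
    corridor = wm & corridor_yz
    seed_roi = corridor & (ii >= 1) & (ii <= 4)  # medial corridor segment
    target_lateral = (ii == nx - 1)  # the whole lateral GM wall
    cx = nx // 2
    target_path = corridor & (ii >= cx - 2) & (ii < cx + 2)

    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = params.voxel_size_mm
    tissue = TissueMaps(
        gm=gm.astype(np.float64),
        wm=wm.astype(np.float64),
        csf=csf.astype(np.float64),
        affine=affine,
    )
    masks = {
        "wm": wm,
        "corridor": corridor,
        "seed_roi": seed_roi,
        "target_lateral": target_lateral,
        "target_path": target_path,
    }
    return tissue, masks


def _truth_field(params: PhantomParams, masks: dict, dirs: np.ndarray) -> np.ndarray:
    """Noiseless density: nominal A-P kernel everywhere in WM, M-L in corridor."""
    n = dirs.shape[0]
    k_ap = params.a_ap * watson_kernel(dirs, (0.0, 1.0, 0.0), params.kappa)
    k_ml = params.a_ml * watson_kernel(dirs, (1.0, 0.0, 0.0), params.kappa)
    truth = np.zeros(params.grid_shape + (n,), dtype=np.float64)
    truth[masks["wm"]] = k_ap
    truth[masks["corridor"]] += k_ml
    return truth


def _subject_rng(params: PhantomParams, subject_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=params.master_seed, spawn_key=(subject_index,))
    return np.random.default_rng(ss)


def subject_wm_profiles(
    params: PhantomParams,
    subject_index: int,
    dirs: np.ndarray,
    corridor_in_wm: np.ndarray,
) -> np.ndarray:
    """Flat (n_wm_voxels, n_dirs) float32 densities for one subject's WM.

    ``corridor_in_wm`` is the corridor indicator restricted to (and ordered
    like) the WM voxels.  This is the generative model proper; callers
    scatter the result into whatever grid or stack layout they need.
    """
    rng = _subject_rng(params, subject_index)
    ap_amp = params.a_ap * float(np.exp(rng.normal(0.0, params.ap_amp_cv)))
    profile_wm = ap_amp * watson_kernel(dirs, (0.0, 1.0, 0.0), params.kappa)
    for _ in range(params.n_noise_kernels):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        amp = rng.uniform(0.0, params.noise_kernel_amp_max)
        profile_wm = profile_wm + amp * watson_kernel(dirs, axis, params.kappa)
    profile_ml = params.a_ml * watson_kernel(dirs, (1.0, 0.0, 0.0), params.kappa)

    n = dirs.shape[0]
    n_wm = corridor_in_wm.shape[0]
    out = np.empty((n_wm, n), dtype=np.float32)
    out[:] = profile_wm
    out[corridor_in_wm] += profile_ml.astype(np.float32)
    if params.noise_sd > 0:
        eps = rng.normal(0.0, params.noise_sd, size=(n_wm, n))
        np.clip(eps, 0.0, None, out=eps)
        out += eps.astype(np.float32)
    return out


def generate_subject(
    params: PhantomParams,
    subject_index: int,
    directions: "DirectionSet | None" = None,
) -> PhantomBundle:
    """One subject's phantom bundle; a pure function of (params, index)."""
    if subject_index < 0:
        raise ParameterError("subject_index must be nonnegative")
    if directions is None:
        directions = default_sphere()
    dirs = directions.vectors
    tissue, masks = _geometry(params)
    truth = _truth_field(params, masks, dirs)

    wm = masks["wm"]
    corridor_in_wm = masks["corridor"][wm]
    dens = np.zeros(params.grid_shape + (dirs.shape[0],), dtype=np.float32)
    dens[wm] = subject_wm_profiles(params, subject_index, dirs, corridor_in_wm)

    fodf = FODFField(
        densities=dens,
        affine=tissue.affine,
        directions=directions,
        name=f"sub-{subject_index:02d}",
    )
    return PhantomBundle(
        fodf=fodf, tissue=tissue, masks=masks, truth=truth,
        subject_id=f"sub-{subject_index:02d}",
    )


def generate_cohort(
    params: PhantomParams,
    directions: "DirectionSet | None" = None,
) -> PhantomCohort:
    """Generate ``n_subjects`` phantoms on a shared grid.

    The corridor, the nominal A-P kernel, and the tissue maps are identical
    across subjects; the A-P amplitude draw, spurious kernels, and noise are
    subject-independent.  The cohort ROI mask is the whole WM.
    """
    if directions is None:
        directions = default_sphere()
    dirs = directions.vectors
    tissue, masks = _geometry(params)
    truth = _truth_field(params, masks, dirs)
    wm = masks["wm"]
    corridor_in_wm = masks["corridor"][wm]

    stack = np.zeros(
        (params.n_subjects,) + params.grid_shape + (dirs.shape[0],), dtype=np.float32
    )
    for i in range(params.n_subjects):
        stack[i][wm] = subject_wm_profiles(params, i, dirs, corridor_in_wm)
    cohort = CohortFODF(
        stack=stack,
        subject_ids=[f"sub-{i:02d}" for i in range(params.n_subjects)],
        roi_mask=wm,
        affine=tissue.affine,
        directions=directions,
    )
    return PhantomCohort(
        cohort=cohort,
        tissue=tissue,
        masks=masks,
        truth=truth,
        params=params,
    )


def params_manifest(params: PhantomParams) -> dict:
    """JSON-serializable record of the generating parameters."""
    d = asdict(params)
    d["grid_shape"] = list(params.grid_shape)
    return d
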