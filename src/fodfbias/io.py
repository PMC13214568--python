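"""Reading and writing the on-disk formats.

* fODF fields: NIfTI-1 4-D (i, j, k, direction) float32 plus a sidecar TSV of
  unit direction vectors (columns x, y, z, one row per direction, in the order
  of the 4th axis).
* Masks: NIfTI-1 uint8.  Tissue maps and density/std volumes: NIfTI-1 float32
  (float64 for std, which carries NaN outside the ROI).
* Streamlines: TrackVis TRK in world (RAS mm) space, with a status TSV keyed
  by streamline index.
* Change histograms: TSV (bin_low, bin_high, increase_mean_count,
  decrease_mean_count) plus a JSON sidecar with per-subject medians and
  exclusion counts.

Loading an fODF floors negative densities to zero and reports how many were
floored together with the raw input range, so the normalization convention of
upstream reconstruction can be audited.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ParameterError
from .odf_core import DirectionSet, FODFField
from .reweight import ChangeHistogram, StdField
from .tracking import StreamlineSet, TissueMaps

__all__ = [
    "LoadReport",
    "save_directions",
    "load_directions",
    "save_fodf",
    "load_fodf",
    "save_mask",
    "load_mask",
    "save_volume",
    "load_volume",
    "save_tissue",
    "load_tissue",
    "save_std_field",
    "save_streamlines",
    "load_streamlines",
    "save_change_histogram",
]


@dataclass
class LoadReport:
    """Record of what loading did to the raw values."""

    path: str
    n_negative_floored: int
    raw_min: float
    raw_max: float

    def to_dict(self) -> dict:
        return {
            "path": self.path,
            "n_negative_floored": self.n_negative_floored,
            "raw_min": self.raw_min,
            "raw_max": self.raw_max,
        }


def save_directions(ds: DirectionSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("x\ty\tz\n")
        for v in ds.vectors:
            fh.write("\t".join("%.17g" % c for c in v) + "\n")


def load_directions(path, name: "str | None" = None) -> DirectionSet:
    vecs = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    if vecs.shape[1] != 3:
        raise ParameterError(f"{path}: expected 3 columns (x, y, z)")
    return DirectionSet(vecs, name=name or Path(path).stem)


def _dirs_sidecar(nii_path) -> Path:
    p = Path(nii_path)
    stem = p.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return p.with_name(stem + "_directions.tsv")


def save_fodf(field: FODFField, nii_path, dirs_path=None) -> None:
    img = nib.Nifti1Image(np.asarray(field.densities, dtype=np.float32), field.affine)
    nib.save(img, str(nii_path))
    save_directions(field.directions, dirs_path or _dirs_sidecar(nii_path))


def load_fodf(nii_path, dirs_path=None):
    """Load an fODF field; returns ``(FODFField, LoadReport)``."""
    img = nib.load(str(nii_path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise ParameterError(f"{nii_path}: expected a 4-D fODF volume")
    report = LoadReport(
        path=str(nii_path),
        n_negative_floored=int((data < 0).sum()),
        raw_min=float(data.min()),
        raw_max=float(data.max()),
    )
    np.clip(data, 0.0, None, out=data)
    ds = load_directions(dirs_path or _dirs_sidecar(nii_path))
    field = FODFField(
        densities=data, affine=np.asarray(img.affine), directions=ds,
        name=Path(str(nii_path)).name,
    )
    return field, report


def save_mask(mask: np.ndarray, affine: np.ndarray, path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    nib.save(img, str(path))


def load_mask(path) -> tuple:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0, np.asarray(img.affine)


def save_volume(data: np.ndarray, affine: np.ndarray, path, dtype=np.float32) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=dtype), affine), str(path))


def load_volume(path) -> tuple:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), np.asarray(img.affine)


def save_tissue(tissue: TissueMaps, out_dir) -> None:
    out = Path(out_dir)
    save_volume(tissue.gm, tissue.affine, out / "gm.nii.gz")
    save_volume(tissue.wm, tissue.affine, out / "wm.nii.gz")
    save_volume(tissue.csf, tissue.affine, out / "csf.nii.gz")


def load_tissue(in_dir) -> TissueMaps:
    p = Path(in_dir)
    gm, affine = load_volume(p / "gm.nii.gz")
    wm, _ = load_volume(p / "wm.nii.gz")
    csf, _ = load_volume(p / "csf.nii.gz")
    return TissueMaps(gm=gm, wm=wm, csf=csf, affine=affine)


def save_std_field(sigma: StdField, affine: np.ndarray, path) -> None:
    save_volume(sigma.sigma, affine, path, dtype=np.float64)


def save_streamlines(s: StreamlineSet, affine: np.ndarray, trk_path, status_path=None) -> None:
    """Write TRK (world space) plus a TSV of per-streamline status and seed."""
    tractogram = nib.streamlines.Tractogram(
        [np.asarray(p, dtype=np.float32) for p in s.polylines],
        affine_to_rasmm=np.eye(4),
    )
    header = nib.streamlines.trk.TrkFile.create_empty_header()
    header["voxel_to_rasmm"] = np.asarray(affine, dtype=np.float32)
    header["voxel_sizes"] = np.linalg.norm(np.asarray(affine)[:3, :3], axis=0)
    header["voxel_order"] = "RAS"
    nib.streamlines.save(nib.streamlines.trk.TrkFile(tractogram, header), str(trk_path))
    if status_path is not None:
        df = pd.DataFrame(
            {
                "streamline": np.arange(len(s)),
                "status": s.statuses,
                "seed_x": s.seeds[:, 0],
                "seed_y": s.seeds[:, 1],
                "seed_z": s.seeds[:, 2],
                "n_points": [len(p) for p in s.polylines],
            }
        )
        df.to_csv(status_path, sep="\t", index=False)


def load_streamlines(trk_path, status_path=None) -> StreamlineSet:
    trk = nib.streamlines.load(str(trk_path))
    polylines = [np.asarray(sl, dtype=np.float64) for sl in trk.streamlines]
    if status_path is not None:
        df = pd.read_csv(status_path, sep="\t")
        statuses = list(df["status"])
        seeds = df[["seed_x", "seed_y", "seed_z"]].to_numpy(dtype=np.float64)
    else:
        statuses = ["valid_gm_termination"] * len(polylines)
        seeds = np.array([p[0] for p in polylines]) if polylines else np.zeros((0, 3))
    return StreamlineSet(polylines=polylines, statuses=statuses, seeds=seeds)


def save_change_histogram(h: ChangeHistogram, tsv_path, json_path=None) -> None:
    df = pd.DataFrame(
        {
            "bin_low": h.bin_edges[:-1],
            "bin_high": h.bin_edges[1:],
            "increase_mean_count": h.increase_counts,
            "decrease_mean_count": h.decrease_counts,
        }
    )
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = {
            "per_subject_medians": [
                {"increase": m[0], "decrease": m[1]} for m in h.per_subject_medians
            ],
            "n_excluded_undefined": h.n_excluded_undefined,
            "increase_flagged": h.increase_flagged,
            "decrease_flagged": h.decrease_flagged,
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)
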