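"""Per-subject voxel-wise correlates aligned on the reference grid.

For every included subject two maps are produced: the local tissue
volume map — the Jacobian determinant of the reference-to-subject
deformation — and the fat-content map — the subject's fat fraction
resampled into reference space.  Stacked over subjects these are the
inputs to the voxel-wise statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .registration import DeformationField, apply_deformation, jacobian_determinant
from .synthetic_cohort import PhantomVolume


def fat_fraction_map(phantom: PhantomVolume) -> np.ndarray:
    """Voxel-wise fat fraction fat/(water+fat) in [0,1]; NaN where the
    total signal is zero (undefined, excluded from analysis)."""
    water = np.asarray(phantom.water, dtype=np.float64)
    fat = np.asarray(phantom.fat, dtype=np.float64)
    if (water < 0).any() or (fat < 0).any():
        raise ValueError("water/fat channels must be non-negative")
    total = water + fat
    ff = np.full(total.shape, np.nan)
    np.divide(fat, total, out=ff, where=total > 0)
    return ff


@dataclass
class VoxelMapStack:
    """Aligned per-subject maps on the reference grid.

    ``volume`` and ``fat`` have shape (n_subjects, nx, ny, nz); subject
    order is identical across both families and matches ``subjects``.
    ``mask`` is the analysis mask: reference body voxels with a defined
    fat value for every subject.
    """

    subjects: list[str]
    volume: np.ndarray
    fat: np.ndarray
    mask: np.ndarray
    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        n = len(self.subjects)
        if self.volume.shape[0] != n or self.fat.shape[0] != n:
            raise ValueError("stack depth must match the subject list")
        if self.volume.shape != self.fat.shape:
            raise ValueError("map families must share one grid")

    @property
    def n(self) -> int:
        return len(self.subjects)

    def family(self, name: str) -> np.ndarray:
        if name == "volume":
            return self.volume
        if name == "fat":
            return self.fat
        raise ValueError(f"unknown map family {name!r}")


def build_stack(
    subject_ids: list[str],
    phantoms: dict[str, PhantomVolume],
    fields: dict[str, DeformationField],
    reference: PhantomVolume,
    use_log_jacobian: bool = False,
) -> VoxelMapStack:
    """Assemble the two map families for the included subjects.

    The fat map is the subject fat fraction warped to reference space
    with trilinear interpolation; NaNs (undefined fat outside the body)
    propagate through interpolation, and any voxel undefined in any
    subject is removed from the analysis mask.
    """
    missing = [s for s in subject_ids if s not in phantoms or s not in fields]
    if missing:
        raise ValueError(f"missing phantom or deformation field for subjects {missing}")
    shape = reference.water.shape
    n = len(subject_ids)
    vol = np.empty((n,) + shape, dtype=np.float32)
    fat = np.empty((n,) + shape, dtype=np.float32)
    for i, sid in enumerate(subject_ids):
        fld = fields[sid]
        prov_id = fld.provenance.get("moving")
        if prov_id is not None and prov_id != sid:
            raise ValueError(
                f"deformation field provenance {prov_id!r} does not match subject {sid!r}"
            )
        jac = jacobian_determinant(fld)
        vol[i] = np.log(np.clip(jac, 1e-6, None)) if use_log_jacobian else jac
        ff = fat_fraction_map(phantoms[sid])
        fat[i] = apply_deformation(fld, ff, interpolation="linear", fill=np.nan)
    mask = (reference.labels > 0) & np.all(np.isfinite(fat), axis=0)
    return VoxelMapStack(
        subjects=list(subject_ids),
        volume=vol,
        fat=fat,
        mask=mask,
        labels=np.asarray(reference.labels),
        spacing=reference.spacing,
    )


# ---------------------------------------------------------------------------
# Persistence: one 4D NIfTI per family + a subjects.csv manifest
# ---------------------------------------------------------------------------

def write_stack(stack: VoxelMapStack, outdir) -> dict[str, str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = np.diag(list(stack.spacing) + [1.0])
    paths = {}
    for fam in ("volume", "fat"):
        arr = np.moveaxis(stack.family(fam), 0, -1)  # subject as 4th axis
        p = outdir / f"stack_{fam}.nii.gz"
        nib.save(nib.Nifti1Image(arr.astype(np.float32), aff), str(p))
        paths[fam] = str(p)
    for name, arr, dt in (
        ("mask", stack.mask, np.uint8),
        ("labels", stack.labels, np.int16),
    ):
        p = outdir / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=dt), aff), str(p))
        paths[name] = str(p)
    mpath = outdir / "subjects.csv"
    pd.DataFrame({"id": stack.subjects}).to_csv(mpath, index=False)
    paths["subjects"] = str(mpath)
    return paths


def read_stack(outdir) -> VoxelMapStack:
    outdir = Path(outdir)
    vol_img = nib.load(str(outdir / "stack_volume.nii.gz"))
    fat_img = nib.load(str(outdir / "stack_fat.nii.gz"))
    spacing = tuple(float(s) for s in vol_img.header.get_zooms()[:3])
    subjects = pd.read_csv(outdir / "subjects.csv")["id"].astype(str).tolist()
    return VoxelMapStack(
        subjects=subjects,
        volume=np.moveaxis(np.asarray(vol_img.dataobj, dtype=np.float32), -1, 0),
        fat=np.moveaxis(np.asarray(fat_img.dataobj, dtype=np.float32), -1, 0),
        mask=np.asarray(nib.load(str(outdir / "mask.nii.gz")).dataobj) > 0,
        labels=np.asarray(nib.load(str(outdir / "labels.nii.gz")).dataobj, dtype=np.int16),
        spacing=spacing,
    )
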