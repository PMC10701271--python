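"""Disk formats: NIfTI volumes with JSON sidecars, sparse-matrix archives.

A case directory holds ``ct.nii.gz``, one ``mask_<name>.nii.gz`` per
structure, optionally ``dose.nii.gz``, and ``case.json`` with the
prescription, size group and generator provenance.  Volumes carry a
diagonal affine built from the grid's LPS origin/spacing; the package reads
back exactly what it writes (no reorientation of foreign data is attempted).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import sparse

from .engine import BeamGeometry, DepositionMatrix, KernelParams
from .grid import PlanCase, VoxelGrid

__all__ = [
    "save_case",
    "load_case",
    "save_grid",
    "load_grid",
    "save_deposition_matrix",
    "load_deposition_matrix",
]


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag(list(grid.spacing) + [1.0])
    aff[:3, 3] = grid.origin
    return aff


def save_grid(grid: VoxelGrid, path: str | Path, dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(grid.data, dtype=dtype), _affine(grid))
    nib.save(img, str(path))


def load_grid(path: str | Path) -> VoxelGrid:
    img = nib.load(str(path))
    aff = img.affine
    return VoxelGrid(
        np.asarray(img.dataobj),
        origin=tuple(aff[:3, 3]),
        spacing=tuple(np.abs(np.diag(aff)[:3])),
    )


def save_case(case: PlanCase, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_grid(case.ct, d / "ct.nii.gz")
    for name, mask in case.structures.items():
        save_grid(mask, d / f"mask_{name}.nii.gz", dtype=np.uint8)
    if case.reference_dose is not None:
        save_grid(case.reference_dose, d / "dose.nii.gz")
    sidecar = {
        "prescription_dose": case.prescription_dose,
        "fractions": case.fractions,
        "size_group": case.size_group,
        "meta": case.meta,
    }
    (d / "case.json").write_text(json.dumps(sidecar, indent=1))


def load_case(directory: str | Path) -> PlanCase:
    d = Path(directory)
    sidecar = json.loads((d / "case.json").read_text())
    ct = load_grid(d / "ct.nii.gz")
    structures = {
        p.name[len("mask_") : -len(".nii.gz")]: load_grid(p)
        for p in sorted(d.glob("mask_*.nii.gz"))
    }
    dose = load_grid(d / "dose.nii.gz") if (d / "dose.nii.gz").exists() else None
    return PlanCase(
        ct=ct,
        structures=structures,
        prescription_dose=sidecar["prescription_dose"],
        fractions=sidecar["fractions"],
        reference_dose=dose,
        size_group=sidecar["size_group"],
        meta=sidecar.get("meta", {}),
    )


def save_deposition_matrix(D: DepositionMatrix, path: str | Path) -> None:
    """Persist matrix (.npz) plus geometry provenance (.json)."""
    path = Path(path)
    sparse.save_npz(path.with_suffix(".npz"), D.matrix)
    meta = {
        "voxel_indices": D.voxel_indices.tolist(),
        "grid_shape": list(D.grid_shape),
        "origin": list(D.origin),
        "spacing": list(D.spacing),
        "kernel": vars(D.kernel),
        "beams": [
            {
                "gantry_angle": b.gantry_angle,
                "isocenter": list(b.isocenter),
                "beamlet_size": b.beamlet_size,
                "beamlet_centers_p": b.beamlet_centers_p.tolist(),
                "beamlet_centers_q": b.beamlet_centers_q.tolist(),
                "source_axis_distance": b.source_axis_distance,
            }
            for b in D.beams
        ],
    }
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_deposition_matrix(path: str | Path) -> DepositionMatrix:
    path = Path(path)
    matrix = sparse.load_npz(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    beams = [
        BeamGeometry(
            gantry_angle=b["gantry_angle"],
            isocenter=tuple(b["isocenter"]),
            beamlet_size=b["beamlet_size"],
            beamlet_centers_p=np.asarray(b["beamlet_centers_p"]),
            beamlet_centers_q=np.asarray(b["beamlet_centers_q"]),
            source_axis_distance=b["source_axis_distance"],
        )
        for b in meta["beams"]
    ]
    return DepositionMatrix(
        matrix=matrix.tocsr(),
        voxel_indices=np.asarray(meta["voxel_indices"]),
        grid_shape=tuple(meta["grid_shape"]),
        origin=tuple(meta["origin"]),
        spacing=tuple(meta["spacing"]),
        beams=beams,
        kernel=KernelParams(**meta["kernel"]),
    )
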