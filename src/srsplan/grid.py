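"""Volumetric containers shared by every pipeline stage.

A :class:`VoxelGrid` is a 3D scalar field (CT in HU, a binary structure mask,
or a dose in Gy) together with its physical geometry: the world coordinate of
the centre of voxel (0, 0, 0) and the voxel pitch, both in millimetres.  Axes
follow the DICOM LPS convention: +x left, +y posterior, +z superior; arrays
are indexed ``data[ix, iy, iz]``.

A :class:`PlanCase` bundles everything that describes one patient-equivalent:
CT, named structure masks, the prescription, and (optionally) a reference
dose of clinical quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["VoxelGrid", "PlanCase"]


@dataclass
class VoxelGrid:
    """A scalar field on a regular axis-aligned 3D grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values.
    origin : tuple of float
        World coordinate (mm, LPS) of the centre of voxel (0, 0, 0).
    spacing : tuple of float
        Voxel pitch (mm) along x, y, z.  Must be positive.
    """

    data: np.ndarray
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"VoxelGrid data must be 3D, got shape {self.data.shape}")
        self.origin = tuple(float(v) for v in self.origin)
        self.spacing = tuple(float(v) for v in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def same_geometry(self, other: "VoxelGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.spacing, other.spacing, atol=atol)
        )

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (..., 3) to world mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm coordinates (..., 3) to fractional voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centres along each axis (1D arrays)."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )  # type: ignore[return-value]

    def copy(self, data: np.ndarray | None = None) -> "VoxelGrid":
        """A new grid with the same geometry; ``data`` replaces the field."""
        return VoxelGrid(
            data=self.data.copy() if data is None else np.asarray(data),
            origin=self.origin,
            spacing=self.spacing,
        )

    # -- mask helpers -------------------------------------------------------
    def mask_volume_cc(self) -> float:
        """Volume of the non-zero region, in cubic centimetres."""
        return float(np.count_nonzero(self.data)) * self.voxel_volume_cc

    def centroid_world(self) -> np.ndarray:
        """World-coordinate centroid of the non-zero region."""
        idx = np.argwhere(self.data)
        if idx.size == 0:
            raise ValueError("cannot take the centroid of an empty mask")
        return self.voxel_to_world(idx.mean(axis=0))


@dataclass
class PlanCase:
    """One patient-equivalent planning case.

    ``structures`` maps structure names (``"pgtv"``, ``"brainstem"``, ...) to
    binary masks on the CT grid.  ``size_group`` is ``"small"`` when the PGTV
    volume is at most 20 cc and ``"large"`` otherwise.
    """

    ct: VoxelGrid
    structures: dict[str, VoxelGrid]
    prescription_dose: float = 30.0
    fractions: int = 5
    reference_dose: VoxelGrid | None = None
    size_group: str | None = None
    meta: dict = field(default_factory=dict)

    PGTV = "pgtv"
    HEAD = "head"

    @property
    def pgtv(self) -> VoxelGrid:
        return self.structures[self.PGTV]

    @property
    def head(self) -> VoxelGrid:
        return self.structures[self.HEAD]

    def oar_names(self) -> list[str]:
        """Structure names excluding the target and the external contour."""
        return [n for n in self.structures if n not in (self.PGTV, self.HEAD)]

    def validate(self) -> None:
        """Check grid-consistency invariants; raise ``ValueError`` on failure."""
        for name, grid in self.structures.items():
            if not grid.same_geometry(self.ct):
                raise ValueError(f"structure {name!r} is not on the CT grid")
        if self.reference_dose is not None and not self.reference_dose.same_geometry(self.ct):
            raise ValueError("reference dose is not on the CT grid")
        if self.PGTV not in self.structures:
            raise ValueError("case has no PGTV structure")

    def with_reference_dose(self, dose: VoxelGrid) -> "PlanCase":
        return replace(self, reference_dose=dose)
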