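"""Case preparation: alignment, normalization, cropping and size grouping.

The preparation protocol mirrors standard practice for voxel-wise dose
prediction on SRS cases:

* structure set and dose are resampled onto the CT grid (masks with
  nearest-neighbour, dose trilinearly);
* CT values are clipped to [-200, 300] HU for contrast, then mapped affinely
  to [-1, 1];
* dose is mapped affinely from [0, dose_ref_max] Gy to [-1, 1];
* the volume is resampled to an isotropic pitch and cropped to a fixed
  window centred on the PGTV centroid (224 x 224 x 32 at 2.5 mm in the
  full-scale preset);
* cases are grouped by PGTV volume: at most 20 cc is "small", above is
  "large".

Structures are encoded into a single integer-label channel with a fixed
priority order (PGTV wins any overlap); a one-hot mode is also available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import PlanCase, VoxelGrid

log = logging.getLogger(__name__)

__all__ = [
    "NormalizationSpec",
    "TensorCase",
    "STRUCTURE_LABELS",
    "align_case",
    "normalize_ct",
    "normalize_dose",
    "denormalize_dose",
    "encode_structures",
    "decode_structures",
    "crop_to_shape",
    "restore_dose",
    "assign_group",
    "tensorize",
]

#: Fixed integer code per structure.  Higher codes take priority when masks
#: overlap; the PGTV always wins.  Code 0 is background (air / unlabelled).
STRUCTURE_LABELS: dict[str, int] = {
    "head": 1,
    "eye_l": 2,
    "eye_r": 3,
    "lens_l": 4,
    "lens_r": 5,
    "optic_nerve_l": 6,
    "optic_nerve_r": 7,
    "optic_chiasm": 8,
    "hypophysis": 9,
    "brainstem": 10,
    "pgtv": 11,
}

SMALL_PGTV_MAX_CC = 20.0


@dataclass
class NormalizationSpec:
    """Affine normalization parameters for CT and dose channels."""

    ct_clip_low: float = -200.0
    ct_clip_high: float = 300.0
    dose_ref_max: float = 42.0  # Gy; 1.4 x the 30 Gy prescription

    def __post_init__(self) -> None:
        if self.ct_clip_low >= self.ct_clip_high:
            raise ValueError("ct_clip_low must be below ct_clip_high")
        if self.dose_ref_max <= 0:
            raise ValueError("dose_ref_max must be positive")


@dataclass
class TensorCase:
    """Network-ready tensors plus the metadata needed to undo them.

    ``inputs`` is channel-stacked ``(C, X, Y, Z)`` with the structure-label
    channel first and the CT channel last; all values lie in [-1, 1].
    ``target`` is the normalized dose ``(X, Y, Z)`` or ``None``.  ``meta``
    carries the inverse-normalization parameters, the crop offset and the
    original grid geometry, which together suffice to restore physical Gy in
    the original CT frame.
    """

    inputs: np.ndarray
    target: np.ndarray | None
    meta: dict = field(default_factory=dict)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.inputs.shape[1:]  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _resample_to(grid: VoxelGrid, ref: VoxelGrid, order: int, fill: float) -> VoxelGrid:
    """Resample ``grid`` onto the geometry of ``ref`` (axis-aligned grids)."""
    if grid.same_geometry(ref):
        return grid
    # world coordinates of ref voxel centres -> fractional indices into grid
    axes = [
        (ref.origin[a] + ref.spacing[a] * np.arange(ref.shape[a]) - grid.origin[a])
        / grid.spacing[a]
        for a in range(3)
    ]
    inside = [(ax >= -0.5) & (ax <= grid.shape[a] - 0.5) for a, ax in enumerate(axes)]
    if not all(m.any() for m in inside):
        raise ValueError("no spatial overlap between grids; cannot align")
    coords = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(
        grid.data.astype(float), np.stack(coords), order=order, mode="constant", cval=fill
    )
    return VoxelGrid(out, origin=ref.origin, spacing=ref.spacing)


def align_case(case: PlanCase) -> PlanCase:
    """Resample structures and dose onto the CT grid.

    Masks use nearest-neighbour interpolation, dose trilinear.  A case whose
    grids already coincide is returned with voxel-identical content.
    """
    structures = {}
    for name, mask in case.structures.items():
        aligned = _resample_to(mask, case.ct, order=0, fill=0.0)
        structures[name] = VoxelGrid(
            aligned.data.astype(np.uint8), case.ct.origin, case.ct.spacing
        )
    dose = case.reference_dose
    if dose is not None:
        dose = _resample_to(dose, case.ct, order=1, fill=0.0)
    return PlanCase(
        ct=case.ct,
        structures=structures,
        prescription_dose=case.prescription_dose,
        fractions=case.fractions,
        reference_dose=dose,
        size_group=case.size_group,
        meta=dict(case.meta),
    )


# ---------------------------------------------------------------------------
# intensity normalization
# ---------------------------------------------------------------------------

def normalize_ct(ct: VoxelGrid | np.ndarray, spec: NormalizationSpec | None = None) -> np.ndarray:
    """Clip HU to [clip_low, clip_high] and map affinely to [-1, 1]."""
    spec = spec or NormalizationSpec()
    x = np.asarray(ct.data if isinstance(ct, VoxelGrid) else ct, dtype=float)
    lo, hi = spec.ct_clip_low, spec.ct_clip_high
    x = np.clip(x, lo, hi)
    return (x - (lo + hi) / 2.0) / ((hi - lo) / 2.0)


def normalize_dose(dose: VoxelGrid | np.ndarray, spec: NormalizationSpec | None = None) -> np.ndarray:
    """Map dose affinely from [0, dose_ref_max] Gy to [-1, 1].

    Doses above the ceiling are clipped with a warning; negative input is
    rejected.
    """
    spec = spec or NormalizationSpec()
    d = np.asarray(dose.data if isinstance(dose, VoxelGrid) else dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative before normalization")
    if np.any(d > spec.dose_ref_max):
        warnings.warn(
            f"dose exceeds dose_ref_max={spec.dose_ref_max} Gy; clipping", stacklevel=2
        )
        log.warning("dose ceiling %.1f Gy exceeded (max %.2f); clipped", spec.dose_ref_max, d.max())
        d = np.minimum(d, spec.dose_ref_max)
    return 2.0 * d / spec.dose_ref_max - 1.0


def denormalize_dose(norm: np.ndarray, spec: NormalizationSpec | None = None) -> np.ndarray:
    """Inverse of :func:`normalize_dose` on the unclipped domain."""
    spec = spec or NormalizationSpec()
    return (np.asarray(norm, dtype=float) + 1.0) * spec.dose_ref_max / 2.0


# ---------------------------------------------------------------------------
# structure encoding
# ---------------------------------------------------------------------------

def encode_structures(
    structures: dict[str, VoxelGrid | np.ndarray],
    labels: dict[str, int] | None = None,
) -> np.ndarray:
    """Merge binary masks into one integer-label array.

    Codes come from ``labels`` (default :data:`STRUCTURE_LABELS`); where masks
    overlap the higher code wins, so the PGTV always survives encoding.
    """
    labels = labels or STRUCTURE_LABELS
    out: np.ndarray | None = None
    for name, code in sorted(labels.items(), key=lambda kv: kv[1]):
        if name not in structures:
            continue
        m = structures[name]
        arr = np.asarray(m.data if isinstance(m, VoxelGrid) else m).astype(bool)
        if out is None:
            out = np.zeros(arr.shape, dtype=np.int16)
        out[arr] = code
    if out is None:
        raise ValueError("no known structures to encode")
    return out


def decode_structures(
    label_map: np.ndarray, labels: dict[str, int] | None = None
) -> dict[str, np.ndarray]:
    """Split an integer-label array back into per-structure binary masks.

    Exact inverse of :func:`encode_structures` for non-overlapping masks; for
    overlapping inputs the higher-priority structure claims shared voxels.
    """
    labels = labels or STRUCTURE_LABELS
    return {name: (label_map == code) for name, code in labels.items() if (label_map == code).any()}


# ---------------------------------------------------------------------------
# cropping
# ---------------------------------------------------------------------------

def _zoom_to_spacing(grid: VoxelGrid, spacing: tuple[float, float, float], order: int, fill: float) -> VoxelGrid:
    factors = tuple(grid.spacing[a] / spacing[a] for a in range(3))
    if np.allclose(factors, 1.0):
        return grid
    out = ndimage.zoom(
        grid.data.astype(float), factors, order=order, mode="constant", cval=fill, grid_mode=True
    )
    # grid_mode=True treats samples as cells: origin shifts to the new cell centre
    new_origin = tuple(
        grid.origin[a] - grid.spacing[a] / 2.0 + spacing[a] / 2.0 for a in range(3)
    )
    return VoxelGrid(out, origin=new_origin, spacing=spacing)


def crop_to_shape(
    case: PlanCase,
    shape: tuple[int, int, int] = (96, 96, 32),
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5),
    norm: NormalizationSpec | None = None,
    label_mode: str = "integer",
) -> TensorCase:
    """Resample to ``spacing``, crop a ``shape`` window centred on the PGTV
    centroid, and normalize all channels.

    The window is padded with air HU / zero dose where it extends beyond the
    volume.  ``meta`` records the crop offset (voxels, possibly negative), the
    resampled and original geometries and the normalization parameters, so
    :func:`restore_dose` can return predictions to the original CT frame.
    """
    norm = norm or NormalizationSpec()
    if case.PGTV not in case.structures or not case.pgtv.data.any():
        raise ValueError("case has an empty PGTV; cannot centre the crop window")

    air_hu = float(case.meta.get("air_hu", -1000.0))
    ct_r = _zoom_to_spacing(case.ct, spacing, order=1, fill=air_hu)
    masks_r = {
        name: _zoom_to_spacing(m, spacing, order=0, fill=0.0)
        for name, m in case.structures.items()
    }
    dose_r = (
        _zoom_to_spacing(case.reference_dose, spacing, order=1, fill=0.0)
        if case.reference_dose is not None
        else None
    )

    centroid = np.argwhere(masks_r[case.PGTV].data).mean(axis=0)
    offset = np.round(centroid - (np.asarray(shape) - 1) / 2.0).astype(int)

    def window(arr: np.ndarray, fill: float) -> np.ndarray:
        out = np.full(shape, fill, dtype=float)
        src_lo = np.maximum(offset, 0)
        src_hi = np.minimum(offset + shape, arr.shape)
        dst_lo = src_lo - offset
        dst_hi = dst_lo + (src_hi - src_lo)
        if np.any(src_hi <= src_lo):
            return out
        out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = arr[
            src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]
        ]
        return out

    label_full = encode_structures(masks_r)
    labels_win = window(label_full.astype(float), 0.0)
    ct_win = window(ct_r.data, air_hu)

    max_code = max(STRUCTURE_LABELS.values())
    if label_mode == "integer":
        struct_channels = [2.0 * labels_win / max_code - 1.0]
    elif label_mode == "onehot":
        struct_channels = [
            (labels_win == code).astype(float) for code in sorted(STRUCTURE_LABELS.values())
        ]
    else:
        raise ValueError(f"unknown label_mode {label_mode!r}")

    inputs = np.stack(struct_channels + [normalize_ct(ct_win, norm)]).astype(np.float32)

    target = None
    if dose_r is not None:
        target = normalize_dose(window(dose_r.data, 0.0), norm).astype(np.float32)

    meta = {
        "dose_ref_max": norm.dose_ref_max,
        "crop_offset": offset.tolist(),
        "crop_shape": list(shape),
        "resampled_shape": list(ct_r.shape),
        "resampled_origin": list(ct_r.origin),
        "resampled_spacing": list(spacing),
        "original_shape": list(case.ct.shape),
        "original_origin": list(case.ct.origin),
        "original_spacing": list(case.ct.spacing),
        "prescription_dose": case.prescription_dose,
        "label_mode": label_mode,
    }
    return TensorCase(inputs=inputs, target=target, meta=meta)


def restore_dose(norm_dose: np.ndarray, meta: dict) -> VoxelGrid:
    """Denormalize a network output and place it back in the original CT frame.

    Voxels outside the crop window are zero.  Negative doses produced by the
    affine inverse are clamped to zero (logged).
    """
    spec = NormalizationSpec(dose_ref_max=meta["dose_ref_max"])
    dose_win = denormalize_dose(norm_dose, spec)
    n_neg = int(np.count_nonzero(dose_win < 0))
    if n_neg:
        log.info("clamped %d negative dose voxels to 0 Gy", n_neg)
    dose_win = np.maximum(dose_win, 0.0)

    offset = np.asarray(meta["crop_offset"])
    res_shape = tuple(meta["resampled_shape"])
    full = np.zeros(res_shape, dtype=float)
    shape = np.asarray(meta["crop_shape"])
    src_lo = np.maximum(offset, 0)
    src_hi = np.minimum(offset + shape, res_shape)
    dst_lo = src_lo - offset
    dst_hi = dst_lo + (src_hi - src_lo)
    full[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]] = dose_win[
        dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]
    ]

    res_grid = VoxelGrid(full, tuple(meta["resampled_origin"]), tuple(meta["resampled_spacing"]))
    orig = VoxelGrid(
        np.zeros(tuple(meta["original_shape"])),
        tuple(meta["original_origin"]),
        tuple(meta["original_spacing"]),
    )
    if res_grid.same_geometry(orig):
        return res_grid
    return _resample_to(res_grid, orig, order=1, fill=0.0)


def assign_group(case: PlanCase) -> str:
    """Classify a case by PGTV volume: at most 20 cc is ``"small"``."""
    if not case.pgtv.data.any():
        raise ValueError("empty PGTV mask")
    return "small" if case.pgtv.mask_volume_cc() <= SMALL_PGTV_MAX_CC else "large"


def tensorize(case: PlanCase, preset: str = "desk", **kwargs) -> TensorCase:
    """Convenience wrapper: align then crop with a named grid preset.

    ``"desk"`` gives 96 x 96 x 32 at 2.5 mm; ``"paper"`` the full-scale
    224 x 224 x 32 at 2.5 mm.
    """
    shapes = {"desk": (96, 96, 32), "paper": (224, 224, 32)}
    if preset not in shapes:
        raise ValueError(f"unknown preset {preset!r}; expected one of {sorted(shapes)}")
    return crop_to_shape(align_case(case), shape=shapes[preset], **kwargs)
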