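"""Synthetic head phantoms: CT, contours and a clinical-quality reference dose.

Each case is a head-like ellipsoid (brain + skull shell + surrounding air) in
Hounsfield units, one spherical PGTV placed in the brain, and the nine OARs
of a standard intracranial SRS structure set (brainstem, optic nerves L/R,
optic chiasm, lenses L/R, eyes L/R, hypophysis) built from geometric
primitives at anatomically plausible offsets.  Anatomical realism is
explicitly not a goal — what matters for exercising the pipeline is the
relative geometry: OARs clearly separated from the target, structures inside
the external contour, voxel masks rasterized by the voxel-centre rule.

The reference dose is produced by the package's own physics: nine
auto-configured beams, a fluence optimization against an idealized
prescription (plateau inside the PGTV, exponential fall-off outside), and a
clinical-style renormalization so that PGTV D95% slightly exceeds the
prescription.  This closed loop keeps every generated case consistent with
the engine that later mimics it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import mimic as mimic_mod
from .engine import KernelParams, auto_configure_beams, build_deposition_matrix, compute_dose
from .evaluate import dose_at_volume
from .grid import PlanCase, VoxelGrid

log = logging.getLogger(__name__)

__all__ = ["PhantomSpec", "generate_case", "make_dataset"]

GRID_PRESETS = {
    "desk": ((96, 96, 32), (2.5, 2.5, 2.5)),
    "paper": ((224, 224, 32), (2.5, 2.5, 2.5)),
}


@dataclass
class PhantomSpec:
    """Geometric and intensity description of one synthetic case.

    All lengths in mm, HU values per tissue class.  ``pgtv_center="random"``
    samples a centre uniformly inside a safe brain region (away from the
    optic apparatus and the brainstem); an explicit centre is validated
    against the head geometry.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 32)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    head_semi_axes: tuple[float, float, float] = (80.0, 95.0, 150.0)
    skull_thickness: float = 5.0
    pgtv_center: tuple[float, float, float] | str = "random"
    pgtv_radius: float = 10.0
    hu_air: float = -1000.0
    hu_skull: float = 700.0
    hu_brain: float = 40.0
    hu_tumor: float = 55.0
    noise_sd: float = 20.0
    prescription_dose: float = 30.0
    fractions: int = 5
    seed: int = 0
    with_reference_dose: bool = True
    #: OAR layout: name -> ("sphere", center, radius) or
    #: ("capsule", p0, p1, radius) or ("cylinder_z", center, radius, half_len)
    oar_layout: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pgtv_radius <= 0:
            raise ValueError("pgtv_radius must be positive")
        if not self.oar_layout:
            self.oar_layout = default_oar_layout()


def default_oar_layout() -> dict:
    """Nine-OAR intracranial layout (mm, LPS, head centred at the origin)."""
    return {
        "eye_l": ("sphere", (31.0, -78.0, 0.0), 11.0),
        "eye_r": ("sphere", (-31.0, -78.0, 0.0), 11.0),
        "lens_l": ("sphere", (31.0, -87.0, 0.0), 3.0),
        "lens_r": ("sphere", (-31.0, -87.0, 0.0), 3.0),
        "optic_nerve_l": ("capsule", (28.0, -68.0, 0.0), (6.0, -32.0, 0.0), 2.5),
        "optic_nerve_r": ("capsule", (-28.0, -68.0, 0.0), (-6.0, -32.0, 0.0), 2.5),
        "optic_chiasm": ("sphere", (0.0, -28.0, 0.0), 5.0),
        "hypophysis": ("sphere", (0.0, -22.0, -10.0), 4.0),
        "brainstem": ("cylinder_z", (0.0, 14.0, 0.0), 9.0, 40.0),
    }


# ---------------------------------------------------------------------------
# rasterization primitives (voxel-centre rule)
# ---------------------------------------------------------------------------

def _coords(grid: VoxelGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ax = grid.coordinate_arrays()
    return np.meshgrid(*ax, indexing="ij")


def _ellipsoid(grid: VoxelGrid, center, semi_axes) -> np.ndarray:
    x, y, z = _coords(grid)
    cx, cy, cz = center
    ax, ay, az = semi_axes
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


def _sphere(grid: VoxelGrid, center, radius) -> np.ndarray:
    return _ellipsoid(grid, center, (radius, radius, radius))


def _capsule(grid: VoxelGrid, p0, p1, radius) -> np.ndarray:
    x, y, z = _coords(grid)
    p = np.stack([x, y, z], axis=-1)
    a, b = np.asarray(p0, float), np.asarray(p1, float)
    ab = b - a
    t = np.clip(((p - a) @ ab) / (ab @ ab), 0.0, 1.0)
    closest = a + t[..., None] * ab
    return ((p - closest) ** 2).sum(axis=-1) <= radius**2


def _cylinder_z(grid: VoxelGrid, center, radius, half_len) -> np.ndarray:
    x, y, z = _coords(grid)
    cx, cy, cz = center
    return ((x - cx) ** 2 + (y - cy) ** 2 <= radius**2) & (np.abs(z - cz) <= half_len)


def _rasterize_oar(grid: VoxelGrid, prim) -> np.ndarray:
    kind = prim[0]
    if kind == "sphere":
        return _sphere(grid, prim[1], prim[2])
    if kind == "capsule":
        return _capsule(grid, prim[1], prim[2], prim[3])
    if kind == "cylinder_z":
        return _cylinder_z(grid, prim[1], prim[2], prim[3])
    raise ValueError(f"unknown primitive {kind!r}")


# ---------------------------------------------------------------------------
# case generation
# ---------------------------------------------------------------------------

def _sample_pgtv_center(
    spec: PhantomSpec, rng: np.random.Generator, ref: VoxelGrid, oar_masks: dict[str, np.ndarray]
) -> np.ndarray:
    """Rejection-sample a PGTV centre in the posterior brain, disjoint from OARs."""
    r = spec.pgtv_radius
    zmax = ref.origin[2] + ref.spacing[2] * (ref.shape[2] - 1)
    z_half = min(12.0, max(0.0, zmax - r - 5.0))
    for _ in range(200):
        c = np.array(
            [
                rng.uniform(-45.0, 45.0),
                rng.uniform(-15.0, 55.0),
                rng.uniform(-z_half, z_half),
            ]
        )
        if not _inside_brain(spec, c, margin=r + spec.skull_thickness + 5.0):
            continue
        trial = _sphere(ref, c, r)
        if any((trial & m).any() for m in oar_masks.values()):
            continue
        return c
    raise RuntimeError("could not place the PGTV; relax the geometry")


def _inside_brain(spec: PhantomSpec, c: np.ndarray, margin: float) -> bool:
    sa = np.asarray(spec.head_semi_axes) - spec.skull_thickness - margin
    if np.any(sa <= 0):
        return False
    return float(((c / sa) ** 2).sum()) <= 1.0


def generate_case(spec: PhantomSpec) -> PlanCase:
    """Generate one synthetic planning case from a :class:`PhantomSpec`.

    Deterministic: an identical spec (including seed) yields a bit-identical
    case.  Raises a geometry error when an explicit PGTV centre falls outside
    the brain.
    """
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.grid_shape, spec.spacing
    origin = tuple(-(shape[a] - 1) * spacing[a] / 2.0 for a in range(3))
    ref = VoxelGrid(np.zeros(shape), origin=origin, spacing=spacing)

    head = _ellipsoid(ref, (0, 0, 0), spec.head_semi_axes)
    inner = tuple(a - spec.skull_thickness for a in spec.head_semi_axes)
    brain = _ellipsoid(ref, (0, 0, 0), inner)
    skull = head & ~brain

    oar_masks = {name: _rasterize_oar(ref, prim) & head for name, prim in spec.oar_layout.items()}
    # lenses sit at the anterior pole of the eyes: carve them out so masks stay disjoint
    for side in ("l", "r"):
        eye, lens = f"eye_{side}", f"lens_{side}"
        if eye in oar_masks and lens in oar_masks:
            oar_masks[eye] &= ~oar_masks[lens]

    if isinstance(spec.pgtv_center, str) and spec.pgtv_center == "random":
        center = _sample_pgtv_center(spec, rng, ref, oar_masks)
    else:
        center = np.asarray(spec.pgtv_center, dtype=float)
        if not _inside_brain(spec, center, margin=spec.pgtv_radius):
            raise ValueError(
                f"PGTV centre {tuple(center)} (radius {spec.pgtv_radius} mm) is outside the head"
            )
    pgtv = _sphere(ref, center, spec.pgtv_radius)
    if any((pgtv & m).any() for m in oar_masks.values()):
        raise ValueError("PGTV overlaps an OAR; choose a different centre")

    ct = np.full(shape, spec.hu_air)
    ct[brain] = spec.hu_brain
    ct[skull] = spec.hu_skull
    ct[pgtv] = spec.hu_tumor
    if spec.noise_sd > 0:
        ct = ct + rng.normal(0.0, spec.noise_sd, size=shape)

    structures = {"head": VoxelGrid(head.astype(np.uint8), origin, spacing)}
    for name, m in oar_masks.items():
        structures[name] = VoxelGrid(m.astype(np.uint8), origin, spacing)
    structures["pgtv"] = VoxelGrid(pgtv.astype(np.uint8), origin, spacing)

    volume_cc = structures["pgtv"].mask_volume_cc()
    case = PlanCase(
        ct=VoxelGrid(ct, origin, spacing),
        structures=structures,
        prescription_dose=spec.prescription_dose,
        fractions=spec.fractions,
        size_group="small" if volume_cc <= 20.0 else "large",
        meta={
            "seed": spec.seed,
            "pgtv_center_mm": [float(v) for v in center],
            "pgtv_radius_mm": spec.pgtv_radius,
            "pgtv_volume_cc": volume_cc,
            "air_hu": spec.hu_air,
        },
    )
    if spec.with_reference_dose:
        case = case.with_reference_dose(reference_dose(case))
    return case


def reference_dose(case: PlanCase, kernel: KernelParams | None = None,
                   d95_margin: float = 1.02) -> VoxelGrid:
    """Clinical-quality reference dose via the package's own planning loop.

    An idealized objective (110% of the prescription inside the PGTV,
    exponential fall-off with an 8 mm constant outside, emulating the steep
    gradients of clinical SRS) is fitted by the
    fluence optimizer on auto-configured beams, and the result is
    renormalized so PGTV D95% equals ``d95_margin`` times the prescription —
    standard plan normalization, with a small margin so downstream
    quantization noise cannot drop coverage below the prescription.
    """
    kernel = kernel or KernelParams()
    beams = auto_configure_beams(case)
    D = build_deposition_matrix(case, beams, kernel)
    rx = case.prescription_dose
    pgtv = case.pgtv.data.astype(bool)
    dist = ndimage.distance_transform_edt(~pgtv, sampling=case.ct.spacing)
    ideal = 1.1 * rx * np.exp(-dist / 8.0)
    ideal[~case.head.data.astype(bool)] = 0.0
    w = mimic_mod.default_importance_weights(case)
    fluence, _ = mimic_mod.optimize_fluence(D, ideal, w, smooth=mimic_mod.MimicConfig().smooth)
    dose = compute_dose(D, fluence.ravel())
    d95 = dose_at_volume(dose, case.pgtv, 95)
    if d95 <= 0:
        raise RuntimeError("reference optimization produced no target coverage")
    scale = d95_margin * rx / d95
    log.info("reference dose renormalized by %.4f (pre-scale D95 %.2f Gy)", scale, d95)
    return dose.copy(dose.data * scale)


def make_dataset(n_small: int, n_large: int, seed: int = 0, **spec_kwargs) -> list[PlanCase]:
    """Generate ``n_small + n_large`` cases with independent geometry draws.

    Small-group radii are drawn from [8, 16] mm (volume at most 20 cc), large
    from [18, 24] mm; each case gets its own child seed so the list is
    reproducible from ``seed`` alone.
    """
    if n_small < 0 or n_large < 0:
        raise ValueError("case counts must be non-negative")
    rng = np.random.default_rng(seed)
    cases: list[PlanCase] = []
    radii = [("small", float(rng.uniform(8.0, 16.0))) for _ in range(n_small)]
    radii += [("large", float(rng.uniform(18.0, 24.0))) for _ in range(n_large)]
    for group, radius in radii:
        child = int(rng.integers(0, 2**31 - 1))
        spec = PhantomSpec(pgtv_radius=radius, seed=child, **spec_kwargs)
        case = generate_case(spec)
        if case.size_group != group:  # rasterization near the 20 cc boundary
            log.warning("case drawn for %s group rasterized as %s", group, case.size_group)
        cases.append(case)
    return cases
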