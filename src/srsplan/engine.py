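"""Beam geometry and the sparse dose-deposition matrix.

The physics core is deliberately simple and fully self-consistent: a
water-equivalent pencil-beam kernel with exponential depth attenuation, a
Gaussian lateral penumbra and an inverse-square factor,

    d(v, b) = exp(-mu_eff * depth_v) * exp(-lat^2 / (2 sigma^2))
              * (SAD / (SAD + depth_v))^2 ,

where ``depth_v`` is the geometric depth of voxel ``v`` below the patient
surface along the beam axis and ``lat`` its lateral distance from beamlet
``b``'s central ray.  Beamlet rays are taken parallel within each field (the
source-axis distance of 1000 mm dwarfs SRS field sizes).  Dose is deposited
only inside the external (head) contour.

Beams are auto-configured coplanar: the primary beam direction joins the head
centre to the PGTV centre (projected to the axial plane), then four more
beams clockwise and four counter-clockwise at 20-degree steps — nine
uniformly spaced fields.  Gantry angles follow IEC 61217: 0 degrees enters
from the anterior, angles increase clockwise viewed from the couch end.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .grid import PlanCase, VoxelGrid

log = logging.getLogger(__name__)

__all__ = [
    "BeamGeometry",
    "KernelParams",
    "DepositionMatrix",
    "auto_configure_beams",
    "build_deposition_matrix",
    "compute_dose",
]


@dataclass
class KernelParams:
    """Pencil-beam kernel parameters (water-equivalent medium)."""

    mu_eff: float = 0.004  # 1/mm, effective linear attenuation of a 6 MV beam
    penumbra_sigma: float = 3.0  # mm, lateral Gaussian spread
    inverse_square: bool = True
    sparsity_floor: float = 1e-4  # drop entries below this fraction of the column max

    def __post_init__(self) -> None:
        if self.mu_eff <= 0 or self.penumbra_sigma <= 0:
            raise ValueError("mu_eff and penumbra_sigma must be positive")


@dataclass
class BeamGeometry:
    """One coplanar field: gantry angle, isocenter and its beamlet lattice.

    The fluence grid lies in the beam's-eye-view plane through the isocenter:
    axis *p* is the in-plane direction perpendicular to the beam axis, axis
    *q* is superior-inferior (machine y).  ``beamlet_centers_p/q`` hold the
    lattice coordinates in mm relative to the isocenter.
    """

    gantry_angle: float
    isocenter: tuple[float, float, float]
    beamlet_size: float = 5.0
    beamlet_centers_p: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beamlet_centers_q: np.ndarray = field(default_factory=lambda: np.zeros(0))
    source_axis_distance: float = 1000.0

    def __post_init__(self) -> None:
        self.gantry_angle = float(self.gantry_angle) % 360.0

    @property
    def n_beamlets(self) -> int:
        return len(self.beamlet_centers_p) * len(self.beamlet_centers_q)

    @property
    def fluence_shape(self) -> tuple[int, int]:
        return (len(self.beamlet_centers_p), len(self.beamlet_centers_q))

    def unit_vectors(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(beam axis, p axis, q axis) unit vectors in LPS world frame.

        IEC 61217 gantry 0 enters from the anterior (-y in LPS); positive
        angles rotate the source toward the patient's left.
        """
        g = np.deg2rad(self.gantry_angle)
        # source sits at iso + SAD * s ; beam axis points from source to iso
        s = np.array([np.sin(g), -np.cos(g), 0.0])
        axis = -s
        p = np.array([np.cos(g), np.sin(g), 0.0])
        q = np.array([0.0, 0.0, 1.0])
        return axis, p, q


@dataclass
class DepositionMatrix:
    """Sparse linear map from beamlet fluence weights to voxel dose (Gy).

    Rows index the voxels listed in ``voxel_indices`` (flat indices into the
    full grid, C order); columns index beamlets, concatenated beam by beam in
    the order of ``beams``.
    """

    matrix: sparse.csr_matrix
    voxel_indices: np.ndarray
    grid_shape: tuple[int, int, int]
    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    beams: list[BeamGeometry]
    kernel: KernelParams

    @property
    def n_voxels(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_beamlets(self) -> int:
        return self.matrix.shape[1]

    def beam_slices(self) -> list[slice]:
        """Column slice of each beam's beamlets."""
        out, start = [], 0
        for b in self.beams:
            out.append(slice(start, start + b.n_beamlets))
            start += b.n_beamlets
        return out


# ---------------------------------------------------------------------------
# beam auto-configuration
# ---------------------------------------------------------------------------

def auto_configure_beams(
    case: PlanCase,
    n_beams: int = 9,
    spacing_deg: float = 20.0,
    beamlet_size: float = 5.0,
    margin: float = 12.0,
) -> list[BeamGeometry]:
    """Auto-configure ``n_beams`` coplanar fields around the PGTV.

    The primary direction joins the head centre to the PGTV centre, projected
    to the axial plane; ``(n_beams - 1) / 2`` further fields are added
    clockwise and the same number counter-clockwise at ``spacing_deg`` steps.
    The beamlet lattice of every field covers the PGTV projection with
    ``margin`` mm on each side.
    """
    if not case.pgtv.data.any() or not case.head.data.any():
        raise ValueError("head and PGTV masks must be non-empty")

    iso = case.pgtv.centroid_world()
    head_c = case.head.centroid_world()
    d = iso - head_c
    d[2] = 0.0  # coplanar: project to the axial plane
    if np.linalg.norm(d) < 1e-6:
        log.warning("PGTV centroid coincides with head centroid; primary beam at gantry 0")
        primary = 0.0
    else:
        d /= np.linalg.norm(d)
        # beam axis (sin g, -cos g, 0) -> gantry of the direction head->PGTV
        primary = float(np.rad2deg(np.arctan2(-d[0], d[1]))) % 360.0

    half = (n_beams - 1) // 2
    offsets = [k * spacing_deg for k in range(-half, n_beams - half)]

    # lattice half-extent from the PGTV's maximal in-plane radius
    pgtv_idx = np.argwhere(case.pgtv.data)
    pts = case.pgtv.voxel_to_world(pgtv_idx) - iso
    r_p = float(np.abs(pts[:, :2]).max()) + margin
    r_q = float(np.abs(pts[:, 2]).max()) + margin

    def lattice(half_extent: float) -> np.ndarray:
        n = max(1, int(np.ceil(2 * half_extent / beamlet_size)))
        return (np.arange(n) - (n - 1) / 2.0) * beamlet_size

    beams = [
        BeamGeometry(
            gantry_angle=primary + off,
            isocenter=tuple(iso),
            beamlet_size=beamlet_size,
            beamlet_centers_p=lattice(r_p),
            beamlet_centers_q=lattice(r_q),
        )
        for off in offsets
    ]
    return beams


# ---------------------------------------------------------------------------
# deposition matrix
# ---------------------------------------------------------------------------

def beamlet_kernel(
    depth: np.ndarray,
    lateral_sq: np.ndarray,
    kernel: KernelParams,
    sad: float = 1000.0,
) -> np.ndarray:
    """Evaluate the pencil-beam kernel (Gy per unit fluence)."""
    w = np.exp(-kernel.mu_eff * depth) * np.exp(-lateral_sq / (2.0 * kernel.penumbra_sigma**2))
    if kernel.inverse_square:
        w = w * (sad / (sad + depth)) ** 2
    return w


def _surface_depth(t: np.ndarray, p: np.ndarray, q: np.ndarray, cell: float) -> np.ndarray:
    """Depth below the surface along the beam axis for every masked voxel.

    Voxels are bucketed into (p, q) cells of width ``cell``; the entry point
    of each ray bundle is the smallest axial coordinate ``t`` seen in its
    cell.
    """
    ip = np.round(p / cell).astype(np.int64)
    iq = np.round(q / cell).astype(np.int64)
    key = (ip - ip.min()) * (iq.max() - iq.min() + 1) + (iq - iq.min())
    order = np.argsort(key, kind="stable")
    ks, ts = key[order], t[order]
    first = np.ones(len(ks), dtype=bool)
    first[1:] = ks[1:] != ks[:-1]
    entry_per_group = np.minimum.reduceat(ts, np.flatnonzero(first))
    group_of = np.cumsum(first) - 1
    entry_sorted = entry_per_group[group_of]
    entry = np.empty_like(t)
    entry[order] = entry_sorted
    return np.maximum(t - entry, 0.0)


def build_deposition_matrix(
    case: PlanCase,
    beams: list[BeamGeometry],
    kernel: KernelParams | None = None,
) -> DepositionMatrix:
    """Assemble the sparse fluence-to-dose operator for a set of fields.

    Dose rows cover the voxels of the external (head) contour.  Entries below
    ``kernel.sparsity_floor`` times their column maximum are dropped.  A beam
    whose lattice misses the head entirely yields a zero column block (with a
    warning).
    """
    kernel = kernel or KernelParams()
    head = case.head.data.astype(bool)
    vox_idx = np.flatnonzero(head.ravel())
    coords = np.argwhere(head)
    world = case.ct.voxel_to_world(coords)

    cutoff_sq = (3.0 * kernel.penumbra_sigma) ** 2
    blocks: list[sparse.csr_matrix] = []
    for beam in beams:
        axis, pvec, qvec = beam.unit_vectors()
        rel = world - np.asarray(beam.isocenter)
        t = rel @ axis
        p = rel @ pvec
        q = rel @ qvec
        depth = _surface_depth(t, p, q, cell=min(case.ct.spacing))

        pb, qb = beam.beamlet_centers_p, beam.beamlet_centers_q
        cols_i: list[np.ndarray] = []
        cols_j: list[np.ndarray] = []
        cols_v: list[np.ndarray] = []
        j = 0
        for pc in pb:
            dp2 = (p - pc) ** 2
            near_p = dp2 <= cutoff_sq
            for qc in qb:
                lat_sq = dp2 + (q - qc) ** 2
                sel = near_p & (lat_sq <= cutoff_sq)
                if sel.any():
                    w = beamlet_kernel(
                        depth[sel], lat_sq[sel], kernel, beam.source_axis_distance
                    )
                    keep = w >= kernel.sparsity_floor * w.max()
                    rows = np.flatnonzero(sel)[keep]
                    cols_i.append(rows)
                    cols_j.append(np.full(len(rows), j))
                    cols_v.append(w[keep])
                j += 1
        if not cols_i:
            warnings.warn(
                f"beam at gantry {beam.gantry_angle:.1f} deg misses the head entirely",
                stacklevel=2,
            )
            block = sparse.csr_matrix((len(vox_idx), beam.n_beamlets))
        else:
            block = sparse.csr_matrix(
                (
                    np.concatenate(cols_v),
                    (np.concatenate(cols_i), np.concatenate(cols_j)),
                ),
                shape=(len(vox_idx), beam.n_beamlets),
            )
        blocks.append(block)

    matrix = sparse.hstack(blocks, format="csr")
    return DepositionMatrix(
        matrix=matrix,
        voxel_indices=vox_idx,
        grid_shape=case.ct.shape,
        origin=case.ct.origin,
        spacing=case.ct.spacing,
        beams=list(beams),
        kernel=kernel,
    )


def compute_dose(D: DepositionMatrix, fluence: np.ndarray) -> VoxelGrid:
    """Dose = D . fluence, reshaped onto the case grid (linear in fluence)."""
    f = np.asarray(fluence, dtype=float).ravel()
    if f.shape[0] != D.n_beamlets:
        raise ValueError(f"fluence has {f.shape[0]} weights, matrix expects {D.n_beamlets}")
    if np.any(f < 0):
        raise ValueError("fluence weights must be non-negative")
    flat = np.zeros(int(np.prod(D.grid_shape)))
    flat[D.voxel_indices] = D.matrix @ f
    return VoxelGrid(flat.reshape(D.grid_shape), origin=D.origin, spacing=D.spacing)
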