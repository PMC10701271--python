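"""Dose mimicking: turn a predicted 3D dose into a deliverable plan.

Pipeline: auto-configure nine coplanar beams -> build the deposition matrix
-> optimize per-beamlet fluence to reproduce the predicted dose voxel-wise
-> sequence each fluence map into dual-layer orthogonal MLC segments ->
recompute the delivered dose from the reconstructed fluence -> verify the
delivery (2D gamma on a simulated detector plane with all fields at gantry
0, and 3D gamma in the patient volume).

Fluence optimization minimizes the importance-weighted squared voxel
disparity

    sum_v w_v (sum_b D_vb f_b - t_v)^2   subject to  f >= 0

by projected gradient descent with a Barzilai-Borwein step and monotone
backtracking, so the recorded objective history is non-increasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import evaluate
from .engine import (
    BeamGeometry,
    DepositionMatrix,
    KernelParams,
    auto_configure_beams,
    beamlet_kernel,
    build_deposition_matrix,
    compute_dose,
)
from .grid import PlanCase, VoxelGrid

log = logging.getLogger(__name__)

__all__ = [
    "FluenceMap",
    "ApertureSegment",
    "ApertureSequence",
    "MimicResult",
    "MimicConfig",
    "default_importance_weights",
    "optimize_fluence",
    "sequence_mlc",
    "deliver",
    "verify_plan",
    "mimic_pipeline",
]


@dataclass
class FluenceMap:
    """Per-beam 2D beamlet-weight arrays (non-negative, unitless)."""

    beams: list[np.ndarray]  # each (n_p, n_q)
    beamlet_size: float = 5.0

    def __post_init__(self) -> None:
        for f in self.beams:
            if not np.all(np.isfinite(f)) or np.any(f < 0):
                raise ValueError("fluence must be finite and non-negative")

    def ravel(self) -> np.ndarray:
        return np.concatenate([f.ravel() for f in self.beams])

    @classmethod
    def from_vector(cls, x: np.ndarray, beams: list[BeamGeometry]) -> "FluenceMap":
        out, start = [], 0
        for b in beams:
            n = b.n_beamlets
            out.append(np.asarray(x[start : start + n]).reshape(b.fluence_shape))
            start += n
        return cls(beams=out, beamlet_size=beams[0].beamlet_size if beams else 5.0)


@dataclass
class ApertureSegment:
    """One deliverable segment of a dual-layer orthogonal MLC.

    ``rows`` holds one (lo, hi) half-open column interval per leaf-pair row
    (layer 1, leaves travelling along q); ``cols`` one (lo, hi) row interval
    per column (layer 2, orthogonal travel).  A beamlet (i, j) is open iff
    ``rows[i][0] <= j < rows[i][1]`` and ``cols[j][0] <= i < cols[j][1]``.
    ``weight`` is the segment's MU-like fluence weight.
    """

    rows: list[tuple[int, int]]
    cols: list[tuple[int, int]]
    weight: float

    def aperture(self, shape: tuple[int, int]) -> np.ndarray:
        open_rows = np.zeros(shape, dtype=bool)
        for i, (lo, hi) in enumerate(self.rows):
            open_rows[i, lo:hi] = True
        open_cols = np.zeros(shape, dtype=bool)
        for j, (lo, hi) in enumerate(self.cols):
            open_cols[lo:hi, j] = True
        return open_rows & open_cols


@dataclass
class ApertureSequence:
    """Deliverable plan: per-beam ordered MLC segments with weights."""

    segments: list[list[ApertureSegment]]  # one list per beam
    fluence_shapes: list[tuple[int, int]]
    beamlet_size: float = 5.0

    def reconstruct(self) -> FluenceMap:
        """Fluence implied by the segments: sum of weight x aperture."""
        beams = []
        for segs, shape in zip(self.segments, self.fluence_shapes):
            f = np.zeros(shape)
            for s in segs:
                f += s.weight * s.aperture(shape)
            beams.append(f)
        return FluenceMap(beams=beams, beamlet_size=self.beamlet_size)

    @property
    def n_segments(self) -> int:
        return sum(len(s) for s in self.segments)


@dataclass
class MimicConfig:
    """Knobs of the mimicking stage."""

    n_beams: int = 9
    beam_spacing_deg: float = 20.0
    beamlet_size: float = 5.0
    kernel: KernelParams = field(default_factory=KernelParams)
    pgtv_weight: float = 10.0
    shell_weight: float = 3.0
    shell_mm: float = 20.0
    n_levels: int = 10
    max_iter: int = 500
    tol: float = 1e-6
    smooth: float = 0.1
    plane_depth_mm: float = 50.0
    plane_pitch_mm: float = 2.5


@dataclass
class MimicResult:
    """Everything produced by one run of the mimicking pipeline."""

    fluence: FluenceMap
    sequence: ApertureSequence
    planned_dose: VoxelGrid
    delivered_dose: VoxelGrid
    objective_history: np.ndarray
    verification: dict
    criteria: dict
    beams: list[BeamGeometry]


# ---------------------------------------------------------------------------
# fluence optimization
# ---------------------------------------------------------------------------

def default_importance_weights(case: PlanCase, shell_mm: float = 20.0,
                               pgtv_w: float = 10.0, shell_w: float = 3.0) -> np.ndarray:
    """Per-voxel importance: PGTV x10, 20 mm shell x3, elsewhere x1."""
    pgtv = case.pgtv.data.astype(bool)
    dist = ndimage.distance_transform_edt(~pgtv, sampling=case.ct.spacing)
    w = np.ones(case.ct.shape)
    w[(dist > 0) & (dist <= shell_mm)] = shell_w
    w[pgtv] = pgtv_w
    return w


def _smoothness_operator(beams: list[BeamGeometry]) -> "sparse_matrix":
    """First-difference operator over each beam's 2D beamlet lattice."""
    from scipy import sparse

    rows, cols, vals = [], [], []
    row = 0
    start = 0
    for b in beams:
        np_, nq = b.fluence_shape
        idx = np.arange(np_ * nq).reshape(np_, nq) + start
        for a, bb in ((idx[:-1, :], idx[1:, :]), (idx[:, :-1], idx[:, 1:])):
            a, bb = a.ravel(), bb.ravel()
            rows.extend(range(row, row + len(a)))
            rows.extend(range(row, row + len(a)))
            cols.extend(a)
            cols.extend(bb)
            vals.extend([1.0] * len(a))
            vals.extend([-1.0] * len(a))
            row += len(a)
        start += np_ * nq
    return sparse.csr_matrix((vals, (rows, cols)), shape=(row, start))


def optimize_fluence(
    D: DepositionMatrix,
    target: VoxelGrid | np.ndarray,
    weights: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    smooth: float = 0.0,
) -> tuple[FluenceMap, np.ndarray]:
    """Non-negative weighted least-squares fluence against a target dose.

    Projected gradient with a Barzilai-Borwein step length and monotone
    backtracking; returns the fluence map and the (non-increasing) objective
    history.  An all-zero target returns zero fluence immediately.

    ``smooth`` adds a fluence-smoothness penalty (relative to the data
    term's curvature) that discourages jagged beamlet patterns; clinical
    optimizers regularize the same way to keep fluence deliverable by a
    finite number of MLC segments.
    """
    t_full = target.data if isinstance(target, VoxelGrid) else np.asarray(target)
    t = t_full.ravel()[D.voxel_indices].astype(float)
    if weights is not None:
        w = np.asarray(weights, dtype=float).ravel()[D.voxel_indices]
        if np.any(w < 0):
            raise ValueError("importance weights must be non-negative")
    else:
        w = np.ones_like(t)

    A = D.matrix
    if not np.any(t > 0):
        f = np.zeros(D.n_beamlets)
        return FluenceMap.from_vector(f, D.beams), np.zeros(1)

    if smooth > 0:
        R = _smoothness_operator(D.beams)
        # scale the penalty by the data term's mean column curvature
        col_curv = float(np.mean(A.power(2).T @ w))
        lam = smooth * col_curv
    else:
        R = None
        lam = 0.0

    def objective(f: np.ndarray, r: np.ndarray) -> float:
        obj = float(w @ (r * r))
        if R is not None:
            rf = R @ f
            obj += lam * float(rf @ rf)
        return obj

    def gradient(f: np.ndarray, r: np.ndarray) -> np.ndarray:
        g = 2.0 * (A.T @ (w * r))
        if R is not None:
            g = g + 2.0 * lam * (R.T @ (R @ f))
        return g

    f = np.zeros(D.n_beamlets)
    r = A @ f - t
    g = gradient(f, r)
    history = [objective(f, r)]
    # initial step from a one-dimensional exact line search along -g
    Ag = A @ g
    denom = float(w @ (Ag * Ag))
    step = float(g @ g) / (2.0 * denom) if denom > 0 else 1.0

    for it in range(max_iter):
        accepted = False
        for _ in range(30):
            f_new = np.maximum(f - step * g, 0.0)
            r_new = A @ f_new - t
            obj_new = objective(f_new, r_new)
            if obj_new <= history[-1] * (1 + 1e-12):
                accepted = True
                break
            step *= 0.5
        if not accepted or np.allclose(f_new, f):
            break
        g_new = gradient(f_new, r_new)
        # Barzilai-Borwein step for the next iteration
        s_vec = f_new - f
        y_vec = g_new - g
        sy = float(s_vec @ y_vec)
        step = float(s_vec @ s_vec) / sy if sy > 1e-30 else step * 2.0
        f, g = f_new, g_new
        history.append(obj_new)
        if len(history) > 1 and history[-2] - history[-1] <= tol * max(history[-2], 1e-30):
            break
    return FluenceMap.from_vector(f, D.beams), np.asarray(history)


# ---------------------------------------------------------------------------
# MLC sequencing
# ---------------------------------------------------------------------------

def _interval(mask_1d: np.ndarray) -> tuple[int, int]:
    idx = np.flatnonzero(mask_1d)
    if idx.size == 0:
        return (0, 0)
    return (int(idx[0]), int(idx[-1]) + 1)


def _longest_run(mask_1d: np.ndarray) -> np.ndarray:
    """Keep only the longest contiguous run of True values."""
    out = np.zeros_like(mask_1d)
    idx = np.flatnonzero(mask_1d)
    if idx.size == 0:
        return out
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[0, breaks + 1]
    ends = np.r_[breaks, idx.size - 1]
    best = np.argmax(ends - starts)
    out[idx[starts[best]] : idx[ends[best]] + 1] = True
    return out


def _cross_convexify(region: np.ndarray, max_iter: int = 10) -> np.ndarray:
    """Largest-run inner approximation that a dual-layer orthogonal MLC can
    shape exactly: iterate longest-run reduction over rows then columns until
    the region is both row- and column-convex (a subset of the input, so the
    aperture never opens beamlets outside the requested level set)."""
    r = region.copy()
    for _ in range(max_iter):
        prev = r.copy()
        for i in range(r.shape[0]):
            r[i, :] = _longest_run(r[i, :])
        for j in range(r.shape[1]):
            r[:, j] = _longest_run(r[:, j])
        if np.array_equal(r, prev):
            break
    return r


def sequence_mlc(
    fluence: FluenceMap, n_levels: int = 10, refit_weights: bool = True
) -> ApertureSequence:
    """Quantize and decompose fluence into dual-layer orthogonal segments.

    Each beam's fluence is rounded to ``n_levels`` equal steps of its own
    maximum, then threshold-decomposed: superlevel set k becomes one segment
    whose layer-1 row intervals and layer-2 column intervals are the
    per-row/per-column supports of the set.  Identical consecutive levels
    are merged into a single weighted segment.  Wherever superlevel sets are
    row- and column-convex the reconstruction equals the quantized map
    exactly, so the error per beamlet is at most half a quantization step.

    With ``refit_weights`` (the default, mirroring the segment-weight
    optimization step of clinical sequencers) the aperture shapes stay
    quantized but the continuous MU weights are refit by non-negative least
    squares against the unquantized fluence, which can only tighten the
    reconstruction bound.
    """
    if n_levels < 1:
        raise ValueError("n_levels must be at least 1")
    all_segments: list[list[ApertureSegment]] = []
    for f in fluence.beams:
        segs: list[ApertureSegment] = []
        fmax = float(f.max())
        if fmax > 0:
            step = fmax / n_levels
            q = np.round(f / step).astype(int)  # 0 .. n_levels
            seen: list[np.ndarray] = []
            for level in range(1, int(q.max()) + 1):
                super_set = q >= level
                if not super_set.any():
                    continue
                # two deliverable shapings of the level set: the row/column
                # interval closure (may open extra beamlets) and the largest
                # cross-convex subset (never does); the weight refit below
                # keeps whichever combination reconstructs best
                candidates = [_cross_convexify(super_set)] if refit_weights else []
                closure = np.zeros_like(super_set)
                rows_c = [_interval(super_set[i, :]) for i in range(super_set.shape[0])]
                cols_c = [_interval(super_set[:, j]) for j in range(super_set.shape[1])]
                for i, (lo, hi) in enumerate(rows_c):
                    closure[i, lo:hi] = True
                for j, (lo, hi) in enumerate(cols_c):
                    closure[:, j] &= np.arange(super_set.shape[0]) >= lo
                    closure[:, j] &= np.arange(super_set.shape[0]) < hi
                candidates.append(closure)
                for region in candidates:
                    if not region.any() or any(np.array_equal(region, s) for s in seen):
                        continue
                    seen.append(region)
                    rows = [_interval(region[i, :]) for i in range(region.shape[0])]
                    cols = [_interval(region[:, j]) for j in range(region.shape[1])]
                    segs.append(ApertureSegment(rows=rows, cols=cols, weight=step))
            if refit_weights and segs:
                from scipy.optimize import nnls

                def refit(segments: list[ApertureSegment]):
                    A = np.stack(
                        [s.aperture(f.shape).ravel().astype(float) for s in segments], axis=1
                    )
                    w, _ = nnls(A, f.ravel())
                    return A, w

                A, w = refit(segs)
                # greedy repair: add cross-convex apertures over the largest
                # under-dosed region until the residual is within the
                # half-step quantization bound (rings and horns need shapes
                # that no single level set provides)
                for _ in range(3 * n_levels):
                    resid = f.ravel() - A @ w
                    if resid.max() <= 0.5 * step:
                        break
                    hot = resid.reshape(f.shape) >= 0.5 * resid.max()
                    labels, n_comp = ndimage.label(hot)
                    sizes = ndimage.sum(hot, labels, range(1, n_comp + 1))
                    region = _cross_convexify(labels == (int(np.argmax(sizes)) + 1))
                    if not region.any() or any(np.array_equal(region, s) for s in seen):
                        break
                    seen.append(region)
                    rows = [_interval(region[i, :]) for i in range(region.shape[0])]
                    cols = [_interval(region[:, j]) for j in range(region.shape[1])]
                    segs.append(ApertureSegment(rows=rows, cols=cols, weight=step))
                    A, w = refit(segs)
                kept = []
                for s, wi in zip(segs, w):
                    if wi > 1e-9:
                        s.weight = float(wi)
                        kept.append(s)
                segs = kept
            elif not refit_weights:
                # merge identical consecutive level sets into one weighted segment
                merged: list[ApertureSegment] = []
                for s in segs:
                    if merged and merged[-1].rows == s.rows and merged[-1].cols == s.cols:
                        merged[-1].weight += s.weight
                    else:
                        merged.append(s)
                segs = merged
        all_segments.append(segs)
    return ApertureSequence(
        segments=all_segments,
        fluence_shapes=[f.shape for f in fluence.beams],
        beamlet_size=fluence.beamlet_size,
    )


def deliver(sequence: ApertureSequence, D: DepositionMatrix) -> VoxelGrid:
    """Delivered dose: the deposition matrix applied to the reconstructed
    (sequenced) fluence."""
    if len(sequence.segments) != len(D.beams):
        raise ValueError("sequence and deposition matrix have different beam counts")
    for shape, beam in zip(sequence.fluence_shapes, D.beams):
        if shape != beam.fluence_shape:
            raise ValueError("sequence fluence shape does not match beam geometry")
    return compute_dose(D, sequence.reconstruct().ravel())


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------

def _plane_dose_map(
    fluence: FluenceMap,
    beams: list[BeamGeometry],
    kernel: KernelParams,
    depth_mm: float,
    pitch_mm: float,
    margin_mm: float = 20.0,
) -> tuple[np.ndarray, float]:
    """Composite dose map with every field recomputed at gantry 0.

    Emulates a 2D detector array in a water slab: a coronal plane at
    ``depth_mm`` water-equivalent depth, detector pitch ``pitch_mm``.  All
    fields share the plane, so the composite is the sum of per-field maps.
    """
    half_p = max(float(np.abs(b.beamlet_centers_p).max()) for b in beams) + margin_mm
    half_q = max(float(np.abs(b.beamlet_centers_q).max()) for b in beams) + margin_mm
    xs = np.arange(-half_p, half_p + pitch_mm, pitch_mm)
    zs = np.arange(-half_q, half_q + pitch_mm, pitch_mm)
    total = np.zeros((len(xs), len(zs)))
    for f, beam in zip(fluence.beams, beams):
        px = beam.beamlet_centers_p
        qz = beam.beamlet_centers_q
        gx = np.exp(-((xs[:, None] - px[None, :]) ** 2) / (2 * kernel.penumbra_sigma**2))
        gz = np.exp(-((zs[:, None] - qz[None, :]) ** 2) / (2 * kernel.penumbra_sigma**2))
        att = beamlet_kernel(
            np.array([depth_mm]), np.array([0.0]), kernel, beam.source_axis_distance
        )[0]
        total += att * (gx @ f @ gz.T)
    return total, pitch_mm


def verify_plan(
    planned: VoxelGrid | None,
    delivered: VoxelGrid | None,
    plane_mode: bool = False,
    *,
    planned_fluence: FluenceMap | None = None,
    delivered_fluence: FluenceMap | None = None,
    beams: list[BeamGeometry] | None = None,
    kernel: KernelParams | None = None,
    config: MimicConfig | None = None,
    dd_percent: float = 3.0,
    dta_mm: float = 3.0,
) -> evaluate.GammaResult:
    """Delivery verification by gamma analysis.

    With ``plane_mode`` off, a full 3D gamma between the planned and
    delivered volumetric doses.  With ``plane_mode`` on, every field is
    recomputed at gantry 0 onto a simulated detector plane (2D array in a
    water slab) for both the planned and the delivered (sequenced) fluence,
    and the composite maps are compared by 2D gamma.
    """
    cfg = config or MimicConfig()
    if plane_mode:
        if planned_fluence is None or delivered_fluence is None or beams is None:
            raise ValueError("plane_mode verification needs fluences and beam geometry")
        k = kernel or cfg.kernel
        ref, pitch = _plane_dose_map(
            planned_fluence, beams, k, cfg.plane_depth_mm, cfg.plane_pitch_mm
        )
        ev, _ = _plane_dose_map(
            delivered_fluence, beams, k, cfg.plane_depth_mm, cfg.plane_pitch_mm
        )
        if ref.max() <= 0:
            raise ValueError("planned plane dose is empty; nothing to verify")
        return evaluate.gamma_analysis(
            ref, ev, spacing=pitch, dd_percent=dd_percent, dta_mm=dta_mm, interp_factor=3
        )
    if planned is None or delivered is None:
        raise ValueError("3D verification needs planned and delivered dose grids")
    if not planned.same_geometry(delivered):
        raise ValueError("planned and delivered doses are not aligned")
    return evaluate.gamma_analysis(
        planned, delivered, dd_percent=dd_percent, dta_mm=dta_mm, interp_factor=1
    )


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def mimic_pipeline(
    case: PlanCase,
    predicted: VoxelGrid,
    config: MimicConfig | None = None,
    D: DepositionMatrix | None = None,
) -> MimicResult:
    """Run the complete mimicking chain on one case.

    Stages: beam auto-configuration, deposition matrix, fluence
    optimization against ``predicted``, dual-layer MLC sequencing, delivered
    dose recomputation, 2D (gantry-0 plane) and 3D gamma verification, and
    the SRS clinical-criteria report on the delivered dose.
    """
    cfg = config or MimicConfig()
    if not predicted.same_geometry(case.ct):
        raise ValueError("[beams] predicted dose is not on the case grid")
    try:
        if D is None:
            beams = auto_configure_beams(
                case, n_beams=cfg.n_beams, spacing_deg=cfg.beam_spacing_deg,
                beamlet_size=cfg.beamlet_size,
            )
            D = build_deposition_matrix(case, beams, cfg.kernel)
        else:
            beams = D.beams
    except Exception as exc:  # pragma: no cover - stage tagging
        raise RuntimeError(f"[beams] {exc}") from exc

    try:
        w = default_importance_weights(case, cfg.shell_mm, cfg.pgtv_weight, cfg.shell_weight)
        fluence, history = optimize_fluence(D, predicted, w, cfg.max_iter, cfg.tol, smooth=cfg.smooth)
    except Exception as exc:
        raise RuntimeError(f"[optimize] {exc}") from exc
    planned_dose = compute_dose(D, fluence.ravel())

    try:
        sequence = sequence_mlc(fluence, cfg.n_levels)
        delivered = deliver(sequence, D)
    except Exception as exc:
        raise RuntimeError(f"[sequence] {exc}") from exc

    try:
        gamma2d = verify_plan(
            None, None, plane_mode=True,
            planned_fluence=fluence, delivered_fluence=sequence.reconstruct(),
            beams=beams, kernel=cfg.kernel, config=cfg,
        )
        gamma3d = verify_plan(planned_dose, delivered, plane_mode=False)
    except Exception as exc:
        raise RuntimeError(f"[verify] {exc}") from exc

    criteria = evaluate.check_clinical_criteria(delivered, case)
    log.info(
        "mimic: %d segments, 2D gamma %.1f%%, 3D gamma %.1f%%, D95 %.2f Gy",
        sequence.n_segments, gamma2d.pass_rate, gamma3d.pass_rate, criteria["d95"],
    )
    return MimicResult(
        fluence=fluence,
        sequence=sequence,
        planned_dose=planned_dose,
        delivered_dose=delivered,
        objective_history=history,
        verification={"gamma_2d": gamma2d, "gamma_3d": gamma3d},
        criteria=criteria,
        beams=beams,
    )
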