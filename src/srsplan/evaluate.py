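"""Dosimetric evaluation: DVH, target/OAR metrics and gamma analysis.

Scalar panel (standard SRS plan-quality set):

* ``Dq%`` — minimum dose received by the hottest q% of a structure, from the
  inverse cumulative DVH with linear interpolation between order statistics;
* ``HI = (D2% - D98%) / Dmean`` — 0 for a perfectly uniform target dose;
* ``CI = |PGTV ∩ V_rx|^2 / (|PGTV| * |V_rx|)`` — Paddick-style conformity,
  1 for a prescription isodose that coincides with the target;
* ``R50% = |V_{0.5 rx}| / |PGTV|`` — intermediate-dose spillage;
* ``D2cm`` — maximum dose on the 20 mm distance shell outside the PGTV
  surface (dose fall-off);
* ``Vx`` — percent of a structure receiving at least x Gy (e.g. brainstem
  V23).

Distribution comparison: point-wise difference statistics (mean, SD, MAE,
also as % of the 30 Gy prescription), isodose Dice coefficients, and the
gamma index (dose-difference / distance-to-agreement, default 3%/3 mm with
global normalization and a 10% lower-dose threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import PlanCase, VoxelGrid

log = logging.getLogger(__name__)

__all__ = [
    "DVHCurve",
    "DoseMetrics",
    "DiffStats",
    "GammaResult",
    "dvh",
    "dose_at_volume",
    "volume_at_dose",
    "conformity_index",
    "homogeneity_index",
    "r50",
    "d2cm",
    "pointwise_stats",
    "isodose_dsc",
    "gamma_analysis",
    "metrics_panel",
    "check_clinical_criteria",
    "cohort_summary",
]


def _arr(x: VoxelGrid | np.ndarray) -> np.ndarray:
    return x.data if isinstance(x, VoxelGrid) else np.asarray(x)


def _mask(x: VoxelGrid | np.ndarray) -> np.ndarray:
    return _arr(x).astype(bool)


# ---------------------------------------------------------------------------
# DVH and dose/volume statistics
# ---------------------------------------------------------------------------

@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram of one structure."""

    dose_bins: np.ndarray  # Gy, bin edges
    cum_volume_fraction: np.ndarray  # fraction of volume receiving >= edge

    def volume_at(self, dose: float) -> float:
        return float(np.interp(dose, self.dose_bins, self.cum_volume_fraction))


def dvh(dose: VoxelGrid | np.ndarray, mask: VoxelGrid | np.ndarray, bin_width: float = 0.1) -> DVHCurve:
    """Cumulative DVH by exhaustive voxel counting within ``mask``."""
    m = _mask(mask)
    if not m.any():
        raise ValueError("empty structure mask")
    d = _arr(dose)[m].astype(float)
    edges = np.arange(0.0, d.max() + 2 * bin_width, bin_width)
    frac = (d[None, :] >= edges[:, None]).mean(axis=1) if d.size < 200_000 else np.array(
        [np.mean(d >= e) for e in edges]
    )
    return DVHCurve(dose_bins=edges, cum_volume_fraction=frac)


def dose_at_volume(dose: VoxelGrid | np.ndarray, mask: VoxelGrid | np.ndarray, q_percent: float) -> float:
    """Dq%: the dose received by at least q% of the structure volume.

    Linear interpolation between sorted voxel doses (inverse cumulative DVH);
    q = 100 returns the minimum dose in the mask, q -> 0 approaches the
    maximum.
    """
    if not 0 < q_percent <= 100:
        raise ValueError("q_percent must be in (0, 100]")
    m = _mask(mask)
    if not m.any():
        raise ValueError("empty structure mask")
    d = np.sort(_arr(dose)[m].astype(float))  # ascending
    n = d.size
    if n == 1:
        return float(d[0])
    # position of the (1 - q/100) quantile on the order statistics
    pos = (1.0 - q_percent / 100.0) * (n - 1)
    lo = int(np.floor(pos))
    hi = min(lo + 1, n - 1)
    w = pos - lo
    return float(d[lo] * (1 - w) + d[hi] * w)


def volume_at_dose(dose: VoxelGrid | np.ndarray, mask: VoxelGrid | np.ndarray, level: float) -> float:
    """Vx: percent of the structure receiving at least ``level`` Gy."""
    m = _mask(mask)
    if not m.any():
        raise ValueError("empty structure mask")
    d = _arr(dose)[m]
    return 100.0 * float(np.count_nonzero(d >= level)) / d.size


# ---------------------------------------------------------------------------
# conformity / homogeneity / fall-off
# ---------------------------------------------------------------------------

def conformity_index(dose: VoxelGrid | np.ndarray, pgtv_mask: VoxelGrid | np.ndarray, rx: float) -> float:
    """Paddick conformity index ``|PGTV ∩ V_rx|^2 / (|PGTV| |V_rx|)``.

    1 for perfect conformity; 0 when the prescription isodose volume is
    empty or disjoint from the target.  Always within [0, 1] by
    Cauchy-Schwarz.
    """
    if rx <= 0:
        raise ValueError("prescription must be positive")
    pgtv = _mask(pgtv_mask)
    if not pgtv.any():
        raise ValueError("empty PGTV mask")
    v_rx = _arr(dose) >= rx
    n_rx = int(np.count_nonzero(v_rx))
    if n_rx == 0:
        log.info("prescription isodose volume is empty; CI = 0")
        return 0.0
    n_overlap = int(np.count_nonzero(v_rx & pgtv))
    return n_overlap**2 / (int(np.count_nonzero(pgtv)) * n_rx)


def homogeneity_index(dose: VoxelGrid | np.ndarray, pgtv_mask: VoxelGrid | np.ndarray) -> float:
    """Homogeneity index ``(D2% - D98%) / Dmean`` over the target."""
    pgtv = _mask(pgtv_mask)
    if not pgtv.any():
        raise ValueError("empty PGTV mask")
    dmean = float(_arr(dose)[pgtv].mean())
    if dmean <= 0:
        raise ValueError("mean target dose is zero; HI undefined")
    return (dose_at_volume(dose, pgtv, 2) - dose_at_volume(dose, pgtv, 98)) / dmean


def r50(dose: VoxelGrid | np.ndarray, pgtv_mask: VoxelGrid | np.ndarray, rx: float) -> float:
    """Ratio of the half-prescription isodose volume to the PGTV volume."""
    pgtv = _mask(pgtv_mask)
    if not pgtv.any():
        raise ValueError("empty PGTV mask")
    return float(np.count_nonzero(_arr(dose) >= 0.5 * rx)) / int(np.count_nonzero(pgtv))


def d2cm(
    dose: VoxelGrid,
    pgtv_mask: VoxelGrid | np.ndarray,
    distance_mm: float = 20.0,
    mode: str = "shell",
) -> float:
    """Maximum dose 2 cm outside the PGTV surface.

    ``mode="shell"`` (default) evaluates the maximum on the distance shell
    ``distance_mm <= d < distance_mm + max(spacing)``; ``mode="beyond"``
    takes the maximum over the whole exterior with ``d >= distance_mm``.
    Distances use the exact Euclidean distance transform with physical
    spacing.
    """
    pgtv = _mask(pgtv_mask)
    if not pgtv.any():
        raise ValueError("empty PGTV mask")
    dist = ndimage.distance_transform_edt(~pgtv, sampling=dose.spacing)
    if mode == "shell":
        shell = (dist >= distance_mm) & (dist < distance_mm + max(dose.spacing))
    elif mode == "beyond":
        shell = dist >= distance_mm
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not shell.any():
        raise ValueError(
            "the 20 mm shell lies outside the dose grid; pad the volume before evaluating D2cm"
        )
    return float(dose.data[shell].max())


# ---------------------------------------------------------------------------
# distribution comparison
# ---------------------------------------------------------------------------

@dataclass
class DiffStats:
    """Point-wise difference statistics of reference minus comparison dose."""

    mean: float
    sd: float
    mae: float
    mean_pct: float
    sd_pct: float
    mae_pct: float
    n: int


def pointwise_stats(
    d_ref: VoxelGrid | np.ndarray,
    d_cmp: VoxelGrid | np.ndarray,
    region_mask: VoxelGrid | np.ndarray | None = None,
    rx: float = 30.0,
) -> DiffStats:
    """Mean, SD and MAE of ``delta = d_ref - d_cmp`` over a region.

    The percent fields are normalized to the prescription dose ``rx``.
    """
    a, b = _arr(d_ref).astype(float), _arr(d_cmp).astype(float)
    if isinstance(d_ref, VoxelGrid) and isinstance(d_cmp, VoxelGrid):
        if not d_ref.same_geometry(d_cmp):
            raise ValueError("dose grids are not aligned")
    elif a.shape != b.shape:
        raise ValueError("dose arrays have different shapes")
    m = _mask(region_mask) if region_mask is not None else np.ones(a.shape, dtype=bool)
    delta = (a - b)[m]
    mean, sd, mae = float(delta.mean()), float(delta.std()), float(np.abs(delta).mean())
    return DiffStats(
        mean=mean,
        sd=sd,
        mae=mae,
        mean_pct=100 * mean / rx,
        sd_pct=100 * sd / rx,
        mae_pct=100 * mae / rx,
        n=int(delta.size),
    )


def isodose_dsc(
    d_a: VoxelGrid | np.ndarray,
    d_b: VoxelGrid | np.ndarray,
    level: float,
) -> float:
    """Dice coefficient of the two >= ``level`` (Gy) isodose volumes.

    When both volumes are empty the distributions agree trivially at that
    level and the DSC is defined as 1 (logged convention).
    """
    a = _arr(d_a) >= level
    b = _arr(d_b) >= level
    na, nb = int(np.count_nonzero(a)), int(np.count_nonzero(b))
    if na + nb == 0:
        log.info("both isodose volumes empty at %.2f Gy; DSC := 1", level)
        return 1.0
    return 2.0 * int(np.count_nonzero(a & b)) / (na + nb)


# ---------------------------------------------------------------------------
# gamma analysis
# ---------------------------------------------------------------------------

@dataclass
class GammaResult:
    """Gamma-index comparison between a reference and an evaluated dose."""

    dd_percent: float
    dta_mm: float
    dose_threshold_percent: float
    normalization: str
    pass_rate: float
    gamma: np.ndarray  # per-reference-point gamma; NaN below threshold
    n_evaluated: int


def gamma_analysis(
    ref: VoxelGrid | np.ndarray,
    ev: VoxelGrid | np.ndarray,
    spacing: float | tuple[float, ...] | None = None,
    dd_percent: float = 3.0,
    dta_mm: float = 3.0,
    dose_threshold_percent: float = 10.0,
    normalization: str = "global",
    interp_factor: int = 1,
    search_radius_factor: float = 3.0,
) -> GammaResult:
    """Gamma index between two dose distributions on a common grid.

    For every reference point above the lower dose threshold,

        gamma = min over evaluated points within ``search_radius_factor * dta``
                of sqrt((dr / dta)^2 + (dD / (dd * Dnorm))^2),

    with ``Dnorm`` the reference maximum (global) or the local reference dose.
    ``interp_factor > 1`` trilinearly up-samples the evaluated distribution
    for sub-voxel distance-to-agreement resolution (use odd factors, which
    keep the coarse voxel centres on the fine lattice).  Works for 2D planes and
    3D volumes.
    """
    r = _arr(ref).astype(float)
    e = _arr(ev).astype(float)
    if r.shape != e.shape:
        raise ValueError("reference and evaluated grids must share a shape")
    if spacing is None:
        spacing = ref.spacing if isinstance(ref, VoxelGrid) else 1.0
    spacing = np.broadcast_to(np.atleast_1d(np.asarray(spacing, float)), (r.ndim,)).copy()

    d_max = float(r.max())
    if d_max <= 0:
        raise ValueError("reference dose is identically zero; gamma undefined")
    threshold = dose_threshold_percent / 100.0 * d_max
    eval_mask = r >= threshold
    if not eval_mask.any():
        raise ValueError("no reference points above the dose threshold")

    if normalization == "global":
        denom_dose = dd_percent / 100.0 * d_max
        local = None
    elif normalization == "local":
        denom_dose = dd_percent / 100.0
        local = r[eval_mask]
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    k = max(1, int(interp_factor))
    if k > 1:
        e_fine = ndimage.zoom(e, k, order=1, grid_mode=True, mode="nearest")
        fine_spacing = spacing / k
    else:
        e_fine = e
        fine_spacing = spacing

    radius = search_radius_factor * dta_mm
    half = np.floor(radius / fine_spacing).astype(int)
    ref_pts = np.argwhere(eval_mask)  # coarse indices
    ref_dose = r[eval_mask]
    # position of each coarse voxel centre on the fine lattice
    base = ref_pts * k + (k - 1) // 2

    gamma_sq = np.full(ref_dose.shape, np.inf)
    shifts = np.meshgrid(*[np.arange(-h, h + 1) for h in half], indexing="ij")
    shifts = np.stack([s.ravel() for s in shifts], axis=1)
    dist_sq_all = ((shifts * fine_spacing) ** 2).sum(axis=1)
    order = np.argsort(dist_sq_all)
    dta_sq = dta_mm**2
    for si in order:
        dist_sq = dist_sq_all[si]
        if dist_sq > radius**2:
            continue
        # early exit: remaining shifts cannot beat an already-passing point
        if np.all(gamma_sq <= dist_sq / dta_sq):
            break
        pos = base + shifts[si]
        ok = np.all((pos >= 0) & (pos < np.asarray(e_fine.shape)), axis=1)
        if not ok.any():
            continue
        ev_dose = e_fine[tuple(pos[ok].T)]
        dd = ref_dose[ok] - ev_dose
        denom = denom_dose if local is None else denom_dose * np.maximum(local[ok], 1e-12)
        cand = dist_sq / dta_sq + (dd / denom) ** 2
        np.minimum.at(gamma_sq, np.flatnonzero(ok), cand)

    gamma_vals = np.sqrt(gamma_sq)
    gamma_map = np.full(r.shape, np.nan)
    gamma_map[eval_mask] = gamma_vals
    pass_rate = 100.0 * float(np.count_nonzero(gamma_vals <= 1.0)) / gamma_vals.size
    return GammaResult(
        dd_percent=dd_percent,
        dta_mm=dta_mm,
        dose_threshold_percent=dose_threshold_percent,
        normalization=normalization,
        pass_rate=pass_rate,
        gamma=gamma_map,
        n_evaluated=int(gamma_vals.size),
    )


# ---------------------------------------------------------------------------
# panels and clinical criteria
# ---------------------------------------------------------------------------

@dataclass
class DoseMetrics:
    """The scalar plan-quality panel for one dose distribution."""

    d2: float
    d98: float
    d95: float
    d50: float
    dmean: float
    dmax: float
    hi: float
    ci: float
    r50: float
    d2cm: float
    v23_brainstem: float | None = None
    oar_dmax: dict[str, float] = field(default_factory=dict)
    oar_dmean: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        out = {
            "D2%": self.d2,
            "D98%": self.d98,
            "D95%": self.d95,
            "D50%": self.d50,
            "Dmean": self.dmean,
            "Dmax": self.dmax,
            "HI": self.hi,
            "CI": self.ci,
            "R50": self.r50,
            "D2cm": self.d2cm,
        }
        if self.v23_brainstem is not None:
            out["brainstem V23"] = self.v23_brainstem
        for name, v in self.oar_dmax.items():
            out[f"{name} Dmax"] = v
        for name, v in self.oar_dmean.items():
            out[f"{name} Dmean"] = v
        return out


def metrics_panel(dose: VoxelGrid, case: PlanCase) -> DoseMetrics:
    """Compute the full scalar panel of ``dose`` against a case's anatomy."""
    pgtv = case.pgtv
    rx = case.prescription_dose
    target = dose.data[pgtv.data.astype(bool)]
    oar_dmax, oar_dmean = {}, {}
    for name in case.oar_names():
        m = case.structures[name].data.astype(bool)
        if m.any():
            oar_dmax[name] = float(dose.data[m].max())
            oar_dmean[name] = float(dose.data[m].mean())
    v23 = None
    if "brainstem" in case.structures and case.structures["brainstem"].data.any():
        v23 = volume_at_dose(dose, case.structures["brainstem"], 23.0)
    return DoseMetrics(
        d2=dose_at_volume(dose, pgtv, 2),
        d98=dose_at_volume(dose, pgtv, 98),
        d95=dose_at_volume(dose, pgtv, 95),
        d50=dose_at_volume(dose, pgtv, 50),
        dmean=float(target.mean()),
        dmax=float(target.max()),
        hi=homogeneity_index(dose, pgtv),
        ci=conformity_index(dose, pgtv, rx),
        r50=r50(dose, pgtv, rx),
        d2cm=d2cm(dose, pgtv),
        v23_brainstem=v23,
        oar_dmax=oar_dmax,
        oar_dmean=oar_dmean,
    )


def check_clinical_criteria(dose: VoxelGrid, case: PlanCase) -> dict:
    """SRS acceptability checks on a dose distribution.

    * target coverage: D95%(PGTV) at least the prescription;
    * high-dose spillage: volume above 105% of the prescription outside the
      PGTV below 15% of the PGTV volume (and the hot spot inside the PGTV);
    * fall-off: D2cm and R50% are reported for review.
    """
    rx = case.prescription_dose
    pgtv = case.pgtv.data.astype(bool)
    d95 = dose_at_volume(dose, case.pgtv, 95)
    hot = dose.data > 1.05 * rx
    spill = int(np.count_nonzero(hot & ~pgtv))
    spill_frac = spill / int(np.count_nonzero(pgtv))
    hotspot_idx = np.unravel_index(int(np.argmax(dose.data)), dose.shape)
    report = {
        "d95": d95,
        "d95_ok": bool(d95 >= rx),
        "high_dose_spillage_fraction": spill_frac,
        "spillage_ok": bool(spill_frac < 0.15),
        "hotspot_in_pgtv": bool(pgtv[hotspot_idx]),
        "d2cm": d2cm(dose, case.pgtv),
        "r50": r50(dose, case.pgtv, rx),
    }
    report["pass"] = report["d95_ok"] and report["spillage_ok"]
    return report


def cohort_summary(panels: list[DoseMetrics]) -> dict[str, str]:
    """Format a cohort of metric panels as ``mean ± SD`` strings."""
    if not panels:
        return {}
    keys = panels[0].as_dict().keys()
    rows = [p.as_dict() for p in panels]
    out = {}
    for k in keys:
        vals = np.array([r[k] for r in rows if k in r], dtype=float)
        out[k] = f"{vals.mean():.2f} ± {vals.std(ddof=1 if len(vals) > 1 else 0):.2f}"
    return out
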