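"""Gamma-index and difference-map comparison of dose distributions.

gamma(r_ref) = min over evaluation points e of
sqrt(|r_e - r_ref|^2 / dta^2 + (D_e - D_ref)^2 / (dD * D_norm)^2)
with D_norm the global maximum of the reference (global mode) or the local
reference dose (local mode).  The evaluation distribution is interpolated
at sub-voxel resolution (step <= dta/10) within a search radius of
3 x dta; a reference voxel passes when gamma <= 1.  The reference is
always the first argument (measurement side), the evaluation the model.

The core is dimension-agnostic: the same search runs on 1D depth-dose
curves and 2D/3D dose grids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .transport import DoseGrid


@dataclass
class GammaCriteria:
    """Dose-difference / distance-to-agreement acceptance criteria."""

    dose_percent: float          # % of D_norm
    dta: float                   # mm
    mode: str = "global"         # global | local
    dose_threshold: float = 0.0  # Gy, on the reference
    search_radius_factor: float = 3.0
    fine_steps_per_dta: int = 10

    def __post_init__(self):
        if self.dose_percent <= 0 or self.dta <= 0:
            raise ValueError("dose_percent and dta must be positive")
        if self.mode not in ("global", "local"):
            raise ValueError("mode must be 'global' or 'local'")


@dataclass
class GammaResult:
    """Gamma map on the reference grid (NaN where below threshold)."""

    gamma: np.ndarray
    criteria: GammaCriteria

    @property
    def passing_fraction(self) -> float:
        """% of non-null (evaluated) voxels with gamma <= 1."""
        valid = np.isfinite(self.gamma)
        if not valid.any():
            raise ValueError("no voxels above the dose threshold")
        return float((self.gamma[valid] <= 1.0).mean() * 100.0)


def _axes_cm(grid) -> list[np.ndarray]:
    if isinstance(grid, DoseGrid):
        return [grid.axis_centers(i) for i in range(grid.dose.ndim)]
    raise TypeError("expected a DoseGrid")


def _offset_lattice(ndim: int, dta_cm: float, radius_cm: float,
                    step_cm: float) -> np.ndarray:
    ax = np.arange(-radius_cm, radius_cm + 0.5 * step_cm, step_cm)
    mesh = np.meshgrid(*([ax] * ndim), indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    dist = np.linalg.norm(pts, axis=1)
    keep = dist <= radius_cm + 1e-12
    pts, dist = pts[keep], dist[keep]
    order = np.argsort(dist)
    return pts[order], dist[order]


def gamma_map(reference: DoseGrid, evaluation: DoseGrid,
              criteria: GammaCriteria) -> GammaResult:
    """Compute the gamma map of evaluation against reference.

    Grids must share the spatial frame (same axes units and origin
    convention); resolutions may differ.  Voxels with reference dose at or
    below the threshold are left undefined (NaN).
    """
    ref_axes = _axes_cm(reference)
    ev_axes = _axes_cm(evaluation)
    if reference.dose.ndim != evaluation.dose.ndim:
        raise ValueError("reference and evaluation dimensionality differ")
    dta_cm = criteria.dta / 10.0  # mm -> cm
    d_norm_global = float(reference.dose.max())
    if d_norm_global <= 0:
        raise ValueError("reference has no positive dose")

    interp = RegularGridInterpolator(
        ev_axes, evaluation.dose, bounds_error=False, fill_value=None)

    thr = criteria.dose_threshold
    valid = reference.dose > thr
    if not valid.any():
        raise ValueError("all reference voxels below the dose threshold")

    mesh = np.meshgrid(*ref_axes, indexing="ij")
    pts = np.stack([m[valid] for m in mesh], axis=1)
    d_ref = reference.dose[valid]
    d_norm = d_norm_global if criteria.mode == "global" else d_ref
    dd_abs = criteria.dose_percent / 100.0 * d_norm

    radius = criteria.search_radius_factor * dta_cm
    step = dta_cm / criteria.fine_steps_per_dta
    offsets, dists = _offset_lattice(reference.dose.ndim, dta_cm, radius, step)

    best = np.full(len(pts), np.inf)
    for off, dist in zip(offsets, dists):
        space2 = (dist / dta_cm) ** 2
        if space2 >= best.max() ** 2:
            break  # offsets are distance-sorted: no voxel can improve
        d_ev = interp(pts + off)
        g2 = space2 + ((d_ev - d_ref) / dd_abs) ** 2
        np.minimum(best, np.sqrt(g2), out=best)

    gmap = np.full(reference.dose.shape, np.nan)
    gmap[valid] = best
    return GammaResult(gamma=gmap, criteria=criteria)


def passing_rate(result: GammaResult, reference: DoseGrid,
                 threshold: float = 0.0) -> float:
    """% of reference voxels above ``threshold`` (Gy) with gamma <= 1."""
    include = (reference.dose > threshold) & np.isfinite(result.gamma)
    if not include.any():
        raise ValueError("threshold excludes all evaluated voxels")
    return float((result.gamma[include] <= 1.0).mean() * 100.0)


def difference_map(reference: DoseGrid, evaluation: DoseGrid,
                   prescription: float) -> tuple[np.ndarray, float, float]:
    """Voxelwise (evaluation - reference) / prescription x 100; plus min/max."""
    if prescription <= 0:
        raise ValueError("prescription must be positive")
    if reference.dose.shape != evaluation.dose.shape:
        raise ValueError("difference map requires identical grids")
    diff = (evaluation.dose - reference.dose) / prescription * 100.0
    return diff, float(diff.min()), float(diff.max())


def gamma_curve(ref_depths, ref_dose, ev_depths, ev_dose,
                criteria: GammaCriteria) -> GammaResult:
    """1D gamma for depth-dose curves (depths in cm, dta in mm)."""
    ref = DoseGrid(np.asarray(ref_dose, dtype=float).reshape(-1, 1, 1),
                   (float(np.diff(ref_depths).mean()), 1.0, 1.0),
                   (float(ref_depths[0]) - 0.5 * float(np.diff(ref_depths).mean()),
                    0.0, 0.0))
    ev = DoseGrid(np.asarray(ev_dose, dtype=float).reshape(-1, 1, 1),
                  (float(np.diff(ev_depths).mean()), 1.0, 1.0),
                  (float(ev_depths[0]) - 0.5 * float(np.diff(ev_depths).mean()),
                   0.0, 0.0))
    # collapse to genuine 1D grids
    ref1 = _as_1d(ref)
    ev1 = _as_1d(ev)
    return gamma_map(ref1, ev1, criteria)


def _as_1d(grid: DoseGrid) -> DoseGrid:
    return DoseGrid(grid.dose.reshape(-1), (grid.voxel_size[0],) + (1.0, 1.0),
                    grid.origin)


def table_row_report(depth_cm: float, reference: DoseGrid,
                     evaluation: DoseGrid, prescription: float,
                     criteria_list=((1.0, 1.0), (2.0, 2.0), (3.0, 3.0))) -> dict:
    """One comparison row: difference min/max and passing rates per criteria.

    Mirrors the planar-detector verification layout: difference map as %
    of the prescription plus gamma passing rates for each (dose %, dta mm)
    pair, threshold 0 Gy on the reference.
    """
    _, dmin, dmax = difference_map(reference, evaluation, prescription)
    row = {"depth_cm": depth_cm, "diff_min_pct": dmin, "diff_max_pct": dmax}
    for dp, dta in criteria_list:
        crit = GammaCriteria(dose_percent=dp, dta=dta, mode="global")
        res = gamma_map(reference, evaluation, crit)
        row[f"gamma_{dp:g}pct_{dta:g}mm"] = res.passing_fraction
    return row
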