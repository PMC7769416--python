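"""Dose-distribution comparison: mean-dose difference and gamma index.

Two metrics: the signed percent difference between mean doses, and the
local-normalization gamma index

    gamma(r) = min over r' of sqrt( ((De(r') - Dr(r)) / (delta * Dr(r)))^2
                                    + (|r' - r| / DTA)^2 )

evaluated at the reference grid's voxel centers with the evaluated grid
sampled by trilinear interpolation on a configurable step.  Voxels below
a low-dose threshold (fraction of the reference maximum) are excluded
from the passing-rate statistics.  gamma <= 1 passes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .grid import VoxelGrid
from .transport import DoseGrid

__all__ = ["GammaCriteria", "ComparisonResult", "mean_dose_delta", "gamma_index",
           "passing_rate", "compare_distributions"]

_PASS_EPS = 1e-6  # float slack on the gamma <= 1 boundary


@dataclass
class GammaCriteria:
    """Local gamma criteria (defaults: 3%/3 mm, 10% threshold)."""

    dose_pct: float = 3.0
    distance_mm: float = 3.0
    low_dose_threshold_pct: float = 10.0
    search_radius_factor: float = 3.0  # search out to factor x DTA
    interp_step_mm: float | None = None  # None -> DTA / 3

    def __post_init__(self) -> None:
        for name in ("dose_pct", "distance_mm", "low_dose_threshold_pct",
                     "search_radius_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.interp_step_mm is None:
            self.interp_step_mm = self.distance_mm / 3.0
        if self.interp_step_mm <= 0:
            raise ValueError("interp_step_mm must be > 0")


@dataclass
class ComparisonResult:
    """Paired-distribution summary: Delta % and gamma passing rate %."""

    delta_pct: float
    gamma_pass_rate_pct: float
    n_evaluable: int
    gamma: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma_pass_rate_pct <= 100.0):
            raise ValueError("passing rate must be in [0, 100]")


def mean_dose_delta(
    mc_mean_gy: float, tps_mean_gy: float, printed_formula: bool = False
) -> float:
    """Signed percent difference between two mean doses.

    Default convention: Delta = (TPS - MC) / MC x 100, i.e. relative to
    the Monte Carlo mean.  ``printed_formula=True`` uses the opposite
    normalization, (MC - TPS) / TPS x 100.
    """
    if printed_formula:
        if tps_mean_gy <= 0:
            raise ValueError("zero reference (TPS) mean")
        return (mc_mean_gy - tps_mean_gy) / tps_mean_gy * 100.0
    if mc_mean_gy <= 0:
        raise ValueError("zero reference (MC) mean")
    return (tps_mean_gy - mc_mean_gy) / mc_mean_gy * 100.0


def _as_grid(dose) -> VoxelGrid:
    return dose.dose if isinstance(dose, DoseGrid) else dose


def gamma_index(
    reference, evaluated, criteria: GammaCriteria | None = None
) -> np.ndarray:
    """Per-voxel local gamma of ``evaluated`` against ``reference``.

    Computed at reference voxel centers; offsets are searched on a cubic
    lattice of pitch ``criteria.interp_step_mm`` out to
    ``search_radius_factor x DTA``, with trilinear interpolation of the
    evaluated grid and early termination once the distance term alone
    exceeds every voxel's current best gamma.  Returns NaN below the
    low-dose threshold.
    """
    criteria = criteria or GammaCriteria()
    ref = _as_grid(reference)
    ev = _as_grid(evaluated)

    r_vals = ref.values.astype(float)
    threshold = criteria.low_dose_threshold_pct / 100.0 * r_vals.max()
    evaluable = r_vals > threshold
    if not evaluable.any():
        raise ValueError("no evaluable voxels: all reference dose below threshold")

    dta = criteria.distance_mm
    radius = criteria.search_radius_factor * dta
    step = criteria.interp_step_mm
    n_off = int(np.floor(radius / step))
    offs_1d = np.arange(-n_off, n_off + 1) * step
    ox, oy, oz = np.meshgrid(offs_1d, offs_1d, offs_1d, indexing="ij")
    offsets = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
    dist = np.linalg.norm(offsets, axis=1)
    keep = dist <= radius + 1e-9
    offsets, dist = offsets[keep], dist[keep]
    order = np.argsort(dist)
    offsets, dist = offsets[order], dist[order]

    # reference voxel centers in evaluated-grid fractional index coordinates
    centers = np.stack(
        [c[evaluable] for c in ref.voxel_centers()], axis=0
    )  # (3, n)
    ev_origin = np.asarray(ev.origin)[:, None]
    ev_spacing = np.asarray(ev.spacing)[:, None]

    dose_tol = criteria.dose_pct / 100.0 * r_vals[evaluable]
    best = np.full(centers.shape[1], np.inf)

    for off, d in zip(offsets, dist):
        dist_term = (d / dta) ** 2
        if dist_term >= np.nanmax(best):
            break
        coords = (centers + off[:, None] - ev_origin) / ev_spacing - 0.5
        sampled = map_coordinates(
            ev.values.astype(float), coords, order=1, mode="constant", cval=np.nan
        )
        cand = ((sampled - r_vals[evaluable]) / dose_tol) ** 2 + dist_term
        np.fmin(best, cand, out=best)

    gamma = np.full(ref.shape, np.nan)
    gamma[evaluable] = np.sqrt(best)
    return gamma


def passing_rate(gamma: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Percent of evaluable voxels with gamma <= 1."""
    g = gamma
    if mask is not None:
        g = np.where(np.asarray(mask, dtype=bool), g, np.nan)
    finite = np.isfinite(g)
    n = int(finite.sum())
    if n == 0:
        raise ValueError("zero evaluable voxels")
    return 100.0 * float(np.sum(g[finite] <= 1.0 + _PASS_EPS)) / n


def compare_distributions(
    reference,
    evaluated,
    criteria: GammaCriteria | None = None,
    mask: np.ndarray | None = None,
    keep_gamma: bool = False,
) -> ComparisonResult:
    """Full comparison: mean-dose Delta plus gamma passing rate."""
    ref = _as_grid(reference)
    ev = _as_grid(evaluated)
    sel = np.ones(ref.shape, dtype=bool) if mask is None else np.asarray(mask, bool)
    delta = mean_dose_delta(
        float(ref.values[sel].mean()), float(ev.values[sel].mean())
    )
    g = gamma_index(reference, evaluated, criteria)
    rate = passing_rate(g, mask)
    n = int(np.isfinite(np.where(sel, g, np.nan)).sum())
    return ComparisonResult(
        delta_pct=delta,
        gamma_pass_rate_pct=rate,
        n_evaluable=n,
        gamma=g if keep_gamma else None,
    )
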