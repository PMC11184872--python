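"""Analytic pencil-beam dose/LET engine.

Computes each spot's dose-to-water and LET contribution on the voxel grid.
The per-spot output contract is :class:`SpotDoseSparse` — sparse voxel
records of (index, dose, LET) — so a Monte Carlo backend could be swapped
in without touching any metric downstream.  The analytic model is
deliberately simple and is NOT commissioned for clinical use:

* range from the Bragg-Kleeman rule ``R = a * E**p`` (water),
* an analytic Bragg curve: a slowly rising entrance plateau that switches
  off over the distal falloff, plus a Gaussian peak of configurable
  peak-to-entrance ratio centered at the nominal range,
* a lateral 2-D Gaussian whose sigma grows with depth,
* LET from the stopping power implied by the range-energy rule, evaluated
  at the local residual range and clipped to a physical span.

Dose is linear in monitor units (MU); ``dose_per_mu`` converts MU to the
laterally integrated dose (Gy·mm²) per unit depth-dose amplitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .cohort import Spot
from .grid import ScalarMap, VoxelGrid, same_grid

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BeamModel:
    """Parameterization of the analytic pencil-beam model (water)."""

    range_a_cm: float = 0.0022   # Bragg-Kleeman R[cm] = a * E[MeV]**p
    range_p: float = 1.77
    # effective peak width: range straggling plus beamline energy spread
    # (pure straggling would be a ~ 0.012; the wider default keeps the
    # spread-out Bragg peak smooth at clinical 2-2.5 mm layer spacing)
    straggling_a: float = 0.024  # sigma_peak[cm] = a * R[cm]**p
    straggling_p: float = 0.935
    peak_entrance_ratio: float = 3.5
    plateau_rise: float = 0.4    # fractional plateau rise from entrance to peak
    falloff_scale: float = 0.3   # distal switch-off width, in units of sigma_peak
    sigma_air_mm: float = 3.0    # lateral sigma at the surface
    sigma_growth: float = 0.03   # lateral broadening per unit depth
    dose_per_mu: float = 1.0     # Gy·mm² per MU per unit depth-dose amplitude
    energy_min_mev: float = 70.0
    energy_max_mev: float = 230.0
    let_min: float = 0.2         # keV/um clip span for scored LET
    let_max: float = 20.0

    def range_mm(self, energy_mev) -> np.ndarray:
        energy_mev = np.asarray(energy_mev, dtype=float)
        return 10.0 * self.range_a_cm * energy_mev**self.range_p

    def energy_for_range_mm(self, range_mm) -> np.ndarray:
        r_cm = np.asarray(range_mm, dtype=float) / 10.0
        return (r_cm / self.range_a_cm) ** (1.0 / self.range_p)

    def sigma_peak_mm(self, range_mm: float) -> float:
        r_cm = range_mm / 10.0
        return 10.0 * self.straggling_a * r_cm**self.straggling_p

    def depth_dose(self, depth_mm, energy_mev: float) -> np.ndarray:
        """Dimensionless depth-dose amplitude (entrance value ~ 1)."""
        z = np.asarray(depth_mm, dtype=float)
        r = float(self.range_mm(energy_mev))
        sp = self.sigma_peak_mm(r)
        t = (z - r) / sp
        switch = expit(-t / self.falloff_scale)
        plateau = (1.0 + self.plateau_rise * np.clip(z, 0.0, None) / r) * switch
        amp = self.peak_entrance_ratio - 0.5 * (1.0 + self.plateau_rise)
        out = plateau + amp * np.exp(-0.5 * t**2)
        return np.where(z < 0, 0.0, out)

    def sigma_mm(self, depth_mm) -> np.ndarray:
        z = np.clip(np.asarray(depth_mm, dtype=float), 0.0, None)
        return np.sqrt(self.sigma_air_mm**2 + (self.sigma_growth * z) ** 2)

    def let_keV_um(self, residual_range_mm) -> np.ndarray:
        """LET (keV/um) at a given residual range, from the stopping power
        dE/dz implied by the Bragg-Kleeman rule, regularized near track end.
        """
        rr_cm = np.clip(np.asarray(residual_range_mm, dtype=float), 0.0, None) / 10.0
        floor = 0.02  # cm; avoids the end-of-range singularity
        rr_cm = rr_cm + floor
        p, a = self.range_p, self.range_a_cm
        s_mev_cm = (rr_cm / a) ** ((1.0 - p) / p) / (p * a)
        return np.clip(0.1 * s_mev_cm, self.let_min, self.let_max)

    def validate(self) -> None:
        """Check model invariants; raises ValueError on violation."""
        energies = np.linspace(self.energy_min_mev, self.energy_max_mev, 50)
        ranges = self.range_mm(energies)
        if not np.all(np.diff(ranges) > 0):
            raise ValueError("range must be monotone increasing in energy")
        for e in (self.energy_min_mev, 120.0, self.energy_max_mev):
            r = float(self.range_mm(e))
            z = np.linspace(0.0, r + 8 * self.sigma_peak_mm(r), 2000)
            dd = self.depth_dose(z, e)
            if np.any(dd < 0):
                raise ValueError("depth dose must be non-negative")
            imax = int(np.argmax(dd))
            if abs(z[imax] - r) > 2.0 * self.sigma_peak_mm(r):
                raise ValueError("depth-dose maximum is not at the Bragg peak")
        zz = np.linspace(0.0, float(self.range_mm(self.energy_max_mev)), 200)
        sig = self.sigma_mm(zz)
        if np.any(sig <= 0) or np.any(np.diff(sig) < 0):
            raise ValueError("lateral sigma must be positive, non-decreasing")
        rr = np.linspace(0.0, float(self.range_mm(self.energy_max_mev)), 400)
        let = self.let_keV_um(rr)
        if np.any(np.diff(let) > 1e-12):
            raise ValueError("LET must be non-increasing in residual range")
        if let.min() < self.let_min - 1e-9 or let.max() > self.let_max + 1e-9:
            raise ValueError("LET outside configured span")


@dataclass
class SpotDoseSparse:
    """One spot's dose/LET contribution as sparse voxel records.

    ``indices`` are flat (C-order) voxel indices on ``grid``; ``dose`` is
    physical Gy per fraction; ``let`` is keV/um at the voxel.
    """

    field_id: str
    spot_id: int
    grid: VoxelGrid
    indices: np.ndarray
    dose: np.ndarray
    let: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.intp)
        self.dose = np.asarray(self.dose, dtype=float)
        if self.let is None:
            self.let = np.zeros_like(self.dose)
        self.let = np.asarray(self.let, dtype=float)
        if not (self.indices.shape == self.dose.shape == self.let.shape):
            raise ValueError("indices, dose and let must have equal length")
        if np.any(self.dose < 0):
            raise ValueError("spot dose entries must be non-negative")
        if self.indices.size and (
            self.indices.min() < 0 or self.indices.max() >= self.grid.n_voxels
        ):
            raise ValueError("voxel indices out of range for grid")

    @property
    def key(self) -> tuple[str, int]:
        return (self.field_id, self.spot_id)


DEFAULT_CUTOFF_GY = 1e-4  # sparse storage cutoff per spot (Gy)


def compute_spot_dose(
    spot: Spot,
    grid: VoxelGrid,
    beam_model: BeamModel | None = None,
    cutoff: float = DEFAULT_CUTOFF_GY,
) -> SpotDoseSparse:
    """Score one spot's dose and LET on the grid.

    dose(v) = mu * dose_per_mu * depth_dose(z_v) * G2(x_v, y_v; sigma(z_v))
    with G2 the normalized lateral 2-D Gaussian centered on the spot axis;
    LET(v) is evaluated from the residual range at the voxel depth.
    Entries with dose below ``cutoff`` are omitted.
    """
    bm = beam_model or BeamModel()
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    if not (bm.energy_min_mev <= spot.energy <= bm.energy_max_mev):
        raise ValueError(
            f"spot {spot.spot_id} of field {spot.field_id}: energy "
            f"{spot.energy} MeV outside commissioned span "
            f"[{bm.energy_min_mev}, {bm.energy_max_mev}] MeV"
        )

    r_mm = float(bm.range_mm(spot.energy))
    sp = bm.sigma_peak_mm(r_mm)

    zw = grid.axis_coords(2)
    depth = zw - grid.entry_z
    k_sel = np.nonzero((depth >= 0) & (depth <= r_mm + 6 * sp))[0]
    if k_sel.size == 0:
        logger.warning("spot %s/%s: beam misses grid in depth",
                       spot.field_id, spot.spot_id)
        return SpotDoseSparse(spot.field_id, spot.spot_id, grid,
                              np.empty(0, np.intp), np.empty(0), np.empty(0))

    depth_k = depth[k_sel]
    sig_k = bm.sigma_mm(depth_k)
    dd_k = bm.depth_dose(depth_k, spot.energy)
    let_k = bm.let_keV_um(r_mm - depth_k)

    sig_max = float(sig_k.max())
    x0, y0 = spot.position
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    i_sel = np.nonzero(np.abs(xs - x0) <= 4.5 * sig_max)[0]
    j_sel = np.nonzero(np.abs(ys - y0) <= 4.5 * sig_max)[0]
    if i_sel.size == 0 or j_sel.size == 0:
        logger.warning("spot %s/%s: beam misses grid laterally",
                       spot.field_id, spot.spot_id)
        return SpotDoseSparse(spot.field_id, spot.spot_id, grid,
                              np.empty(0, np.intp), np.empty(0), np.empty(0))

    dx2 = (xs[i_sel] - x0) ** 2
    dy2 = (ys[j_sel] - y0) ** 2
    r2 = dx2[:, None] + dy2[None, :]  # (ni, nj)

    var = sig_k**2  # (nk,)
    lateral = np.exp(-0.5 * r2[:, :, None] / var) / (2.0 * np.pi * var)
    dose = spot.mu * bm.dose_per_mu * dd_k * lateral  # (ni, nj, nk)

    keep = dose >= cutoff if cutoff > 0 else dose > 0
    ii, jj, kk = np.nonzero(keep)
    flat = grid.ravel(i_sel[ii], j_sel[jj], k_sel[kk])
    return SpotDoseSparse(
        field_id=spot.field_id,
        spot_id=spot.spot_id,
        grid=grid,
        indices=flat,
        dose=dose[keep],
        let=let_k[kk],
    )


def point_dose(
    spots: list[Spot],
    points: np.ndarray,
    beam_model: BeamModel | None = None,
    entry_z: float = 0.0,
) -> np.ndarray:
    """Evaluate the analytic dose of a set of spots at arbitrary world
    points (mm); used for MU calibration and as a quadrature-free probe.
    """
    bm = beam_model or BeamModel()
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    total = np.zeros(pts.shape[0])
    for s in spots:
        depth = pts[:, 2] - entry_z
        sig = bm.sigma_mm(depth)
        dd = bm.depth_dose(depth, s.energy)
        r2 = (pts[:, 0] - s.position[0]) ** 2 + (pts[:, 1] - s.position[1]) ** 2
        total += s.mu * bm.dose_per_mu * dd * np.exp(-0.5 * r2 / sig**2) / (
            2.0 * np.pi * sig**2
        )
    return total if points.ndim > 1 else total


def _check_common_grid(spot_doses: list[SpotDoseSparse]) -> VoxelGrid:
    if not spot_doses:
        raise ValueError("no spot doses given")
    g = spot_doses[0].grid
    for sd in spot_doses[1:]:
        if not same_grid(sd.grid, g):
            raise ValueError("spot doses are on mixed grids")
    return g


def accumulate_dose(
    spot_doses: list[SpotDoseSparse], grid: VoxelGrid | None = None
) -> ScalarMap:
    """Voxel-wise sum of per-spot doses (physical Gy per fraction)."""
    if not spot_doses:
        if grid is None:
            raise ValueError("empty spot list requires an explicit grid")
        return ScalarMap(grid, np.zeros(grid.dims), units="Gy", name="dose")
    g = _check_common_grid(spot_doses)
    if grid is not None and not same_grid(g, grid):
        raise ValueError("spot doses are not on the requested grid")
    flat = np.zeros(g.n_voxels)
    for sd in spot_doses:
        np.add.at(flat, sd.indices, sd.dose)
    return ScalarMap(g, flat.reshape(g.dims), units="Gy", name="dose")


def accumulate_letd(spot_doses: list[SpotDoseSparse]) -> ScalarMap:
    """Dose-averaged LET: LET_d(v) = sum_s d_s(v) L_s(v) / sum_s d_s(v).

    Voxels with zero accumulated dose have undefined LET_d and are NaN.
    """
    g = _check_common_grid(spot_doses)
    num = np.zeros(g.n_voxels)
    den = np.zeros(g.n_voxels)
    for sd in spot_doses:
        np.add.at(num, sd.indices, sd.dose * sd.let)
        np.add.at(den, sd.indices, sd.dose)
    with np.errstate(invalid="ignore", divide="ignore"):
        letd = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return ScalarMap(g, letd.reshape(g.dims), units="keV/um", name="LETd")


def scale_mu(spot_dose: SpotDoseSparse, factor: float) -> SpotDoseSparse:
    """Rescale a sparse spot dose as if its MU were multiplied by factor."""
    if factor < 0:
        raise ValueError("factor must be >= 0")
    return replace(spot_dose, dose=spot_dose.dose * factor,
                   indices=spot_dose.indices.copy(), let=spot_dose.let.copy())
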