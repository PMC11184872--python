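"""Voxel-wise maximum dose rate (MDR) and near-maximum metrics.

The instantaneous dose rate a voxel experiences during a spot is the ratio
of the spot's dose to the voxel and the spot's beam-on duration.  MDR(v)
is the maximum of that ratio over all spots in scope (a whole plan or one
field); spots contributing no dose to a voxel contribute nothing.  A voxel
enters the MDR map only if its total per-fraction dose reaches a dose
threshold (default 1 cGy RBE-weighted per fraction) — MDR is sensitive to
this threshold, so it is explicit configuration, not a constant.

``near_max`` is the DVH-style near-maximum: the smallest value reached or
exceeded by a given fraction (default 2%) of the structure volume.  It is
the single routine behind D2, LET2, variable-RBE D2 and MDR2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose_engine import SpotDoseSparse, _check_common_grid
from .grid import ScalarMap, StructureMask, VoxelGrid, same_grid
from .timing import SpotTimingRecord


@dataclass(frozen=True)
class DoseRateConfig:
    """Dose-rate metric configuration.

    dose_threshold
        Gy per fraction; voxels below it are excluded from the MDR map
        (default 0.01 Gy = 1 cGy).  With ``gate_mode="total"`` (default)
        the threshold applies to the voxel's total per-fraction RBE dose;
        with ``"per_spot"`` it gates individual spot contributions instead.
    rbe_constant
        Constant RBE weighting applied to doses and rates (default 1.1);
        set to 1.0 for physical Gy/s.
    percentile_level
        Volume percentage for near-maximum metrics (default 2 -> MDR2/D2).
    display_threshold
        Gy_RBE/s; presentation-only cutoff for overlay exports, never used
        in metric values (default 3).
    """

    dose_threshold: float = 0.01
    rbe_constant: float = 1.1
    percentile_level: float = 2.0
    display_threshold: float = 3.0
    gate_mode: str = "total"

    def __post_init__(self) -> None:
        if self.dose_threshold < 0:
            raise ValueError("dose_threshold must be >= 0")
        if not (0.0 < self.percentile_level < 100.0) and self.percentile_level != 100.0:
            raise ValueError("percentile_level must be in (0, 100]")
        if self.gate_mode not in ("total", "per_spot"):
            raise ValueError("gate_mode must be 'total' or 'per_spot'")


@dataclass
class MDRMap:
    """Maximum-dose-rate map on a grid.

    ``values`` are Gy_RBE/s (NaN outside the valid set); ``valid`` marks
    voxels whose gating dose reached ``threshold_used``; ``provenance`` is
    ``"plan"`` or the field id the map was computed for.
    """

    grid: VoxelGrid
    values: np.ndarray
    valid: np.ndarray
    provenance: str
    threshold_used: float
    units: str = "Gy_RBE/s"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.grid.dims or self.valid.shape != self.grid.dims:
            raise ValueError("MDR map shape does not match grid dims")
        finite = self.values[self.valid]
        if finite.size and (np.any(~np.isfinite(finite)) or np.any(finite < 0)):
            raise ValueError("MDR values must be finite and >= 0 where valid")

    def as_scalar_map(self) -> ScalarMap:
        return ScalarMap(self.grid, self.values, units=self.units,
                         name=f"MDR[{self.provenance}]")

    def masked_above(self, display_threshold: float) -> ScalarMap:
        """Overlay view: values below the display threshold removed (NaN).
        Presentation only; metric values never depend on it."""
        vals = np.where(self.valid & (self.values >= display_threshold),
                        self.values, np.nan)
        return ScalarMap(self.grid, vals, units=self.units,
                         name=f"MDR[{self.provenance}]>={display_threshold}")


def spot_dose_rate(
    spot_dose: SpotDoseSparse,
    timing: SpotTimingRecord,
    rbe_constant: float = 1.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Sparse dose rate of one spot: rate(v) = rbe * d_s(v) / t_s.

    Returns (flat voxel indices, rates in Gy_RBE/s).
    """
    if timing is None:
        raise ValueError(
            f"missing timing for spot {spot_dose.spot_id} of field "
            f"{spot_dose.field_id}"
        )
    if timing.key != spot_dose.key:
        raise ValueError(
            f"timing record {timing.key} does not match spot {spot_dose.key}"
        )
    return spot_dose.indices, rbe_constant * spot_dose.dose / timing.duration_s


def compute_mdr(
    spot_doses: list[SpotDoseSparse],
    timings: dict[tuple[str, int], SpotTimingRecord],
    config: DoseRateConfig | None = None,
    scope: str = "plan",
) -> MDRMap:
    """Maximum dose rate per voxel over all spots in scope.

    ``scope`` is ``"plan"`` (all given spots) or a field id (that field's
    spots only).  The valid set is gated by the scope's total per-fraction
    RBE dose against ``config.dose_threshold`` (or, with
    ``gate_mode="per_spot"``, by individual contributions).
    """
    cfg = config or DoseRateConfig()
    if scope != "plan":
        spot_doses = [sd for sd in spot_doses if sd.field_id == scope]
    if not spot_doses:
        raise ValueError(f"empty scope {scope!r}: no spots to compute MDR from")
    grid = _check_common_grid(spot_doses)

    mdr = np.zeros(grid.n_voxels)
    total = np.zeros(grid.n_voxels)
    qualifying = np.zeros(grid.n_voxels, dtype=bool)
    for sd in spot_doses:
        rec = timings.get(sd.key)
        idx, rates = spot_dose_rate(sd, rec, cfg.rbe_constant)
        contrib = cfg.rbe_constant * sd.dose
        np.add.at(total, idx, contrib)
        if cfg.gate_mode == "per_spot":
            ok = contrib >= cfg.dose_threshold
            idx, rates = idx[ok], rates[ok]
            qualifying[idx] = True
        np.maximum.at(mdr, idx, rates)

    if cfg.gate_mode == "total":
        valid = total >= cfg.dose_threshold
    else:
        valid = qualifying
    values = np.where(valid, mdr, np.nan)
    return MDRMap(grid=grid, values=values.reshape(grid.dims),
                  valid=valid.reshape(grid.dims), provenance=scope,
                  threshold_used=cfg.dose_threshold)


def near_max(
    vmap: ScalarMap | MDRMap,
    mask: StructureMask,
    level: float = 2.0,
) -> float:
    """Near-maximum value over a structure: the smallest value m such that
    the fraction of eligible structure volume with value >= m is at least
    ``level``/100.

    For MDR maps only valid voxels are eligible; for dose/LET maps all
    masked voxels with a defined (non-NaN) value are.  Over discrete
    voxels this is the k-th largest eligible value with
    k = ceil(n * level / 100); ties at the boundary value are included by
    construction.  level -> 0+ gives the masked maximum, level = 100 the
    masked minimum.
    """
    if not (0.0 < level <= 100.0):
        raise ValueError("level must be in (0, 100]")
    if not same_grid(vmap.grid, mask.grid):
        raise ValueError(
            f"mask {mask.name!r} and map are on different grids"
        )
    eligible = mask.voxels & np.isfinite(vmap.values)
    if isinstance(vmap, MDRMap):
        eligible &= vmap.valid
    vals = vmap.values[eligible]
    if vals.size == 0:
        name = getattr(vmap, "provenance", None) or getattr(vmap, "name", "map")
        raise ValueError(
            f"structure {mask.name!r} has no eligible voxels on map {name!r}"
        )
    k = max(1, math.ceil(vals.size * level / 100.0))
    return float(np.partition(vals, vals.size - k)[vals.size - k])


def fieldwise_mdr2_table(
    field_maps: dict[tuple[str, str], MDRMap],
    masks: dict[str, StructureMask],
    level: float = 2.0,
) -> pd.DataFrame:
    """Per-(case, field, structure) MDR2 table.

    ``field_maps`` maps (case_id, field_id) to that field's MDR map; every
    field of every case must be present (missing maps raise via the caller
    supplying them).  The default 8-case/28-field cohort with the three
    optic structures yields 84 rows.
    """
    if not field_maps:
        raise ValueError("no field MDR maps given")
    rows = []
    for (case_id, field_id), fmap in field_maps.items():
        if fmap is None:
            raise ValueError(f"missing MDR map for field {field_id} of "
                             f"case {case_id}")
        for sname, mask in masks.items():
            rows.append((case_id, field_id, sname, "MDR2",
                         near_max(fmap, mask, level), fmap.units))
    return pd.DataFrame(
        rows, columns=["case_id", "field_id", "structure", "metric",
                       "value", "units"],
    )


def dose_above_dose_rate(
    spot_doses: list[SpotDoseSparse],
    timings: dict[tuple[str, int], SpotTimingRecord],
    mask: StructureMask,
    rate_threshold: float,
    rbe_constant: float = 1.1,
) -> tuple[float, float]:
    """Cumulative dose delivered at or above a dose-rate threshold.

    Sums, over masked voxels, only those spot contributions whose rate
    meets the threshold; returns (Gy_RBE, percent of total masked dose).
    Monotone non-increasing in the threshold; threshold 0 returns 100%.
    """
    if rate_threshold < 0:
        raise ValueError("rate_threshold must be >= 0")
    grid = _check_common_grid(spot_doses)
    if not same_grid(mask.grid, grid):
        raise ValueError("mask and spot doses are on different grids")
    if mask.n_voxels == 0:
        raise ValueError(f"structure {mask.name!r} mask is empty")
    flat_mask = mask.voxels.ravel()
    above = 0.0
    total = 0.0
    for sd in spot_doses:
        idx, rates = spot_dose_rate(sd, timings.get(sd.key), rbe_constant)
        in_mask = flat_mask[idx]
        contrib = rbe_constant * sd.dose[in_mask]
        total += float(contrib.sum())
        above += float(contrib[rates[in_mask] >= rate_threshold].sum())
    pct = 100.0 * above / total if total > 0 else 0.0
    return above, pct
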