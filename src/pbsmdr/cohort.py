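"""Synthetic treatment-plan cohort generator.

Emulates an 8-case intracranial cohort: meningioma-like targets close to
the optic apparatus, prescriptions between 50.4 and 55.8 Gy_RBE delivered
at 1.8-1.93 Gy_RBE per fraction, 3-4 fields per plan (28 fields in all).
Two cases are "index" cases carrying a planted high-dose-rate signal: one
designated hot field per index case whose spots nearest the left optic
nerve receive elevated monitor units, while the field's beam current is
raised by the same factor so spot durations stay typical and the elevation
shows up as dose rate, not as delivery time.

Spot maps are target-conformal in a simple sense: energy layers whose
Bragg peaks span the CTV in depth, and per layer a lateral grid of spots
covering the CTV cross-section plus a margin.  This is a planning stand-in,
not a reproduction of any clinical optimizer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import StructureMask, VoxelGrid
from . import phantom
from .phantom import Primitive

SPOT_CSV_COLUMNS = ["field_id", "spot_id", "energy_mev", "x_mm", "y_mm", "mu"]


@dataclass
class Spot:
    """One pencil-beam spot: lateral position at the isocenter plane,
    nominal energy, and monitor units (proportional to protons)."""

    field_id: str
    spot_id: int
    position: tuple[float, float]  # (x, y) mm
    energy: float                  # MeV
    mu: float                      # monitor units
    hot: bool = False              # generator metadata: mu was elevated

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"spot {self.spot_id}: mu must be > 0")


@dataclass
class FieldPlan:
    """One treatment field: its spots plus the delivery current scale used
    by the timing model (hot fields run at raised current)."""

    field_id: str
    spots: list[Spot]
    current_scale: float = 1.0
    hot: bool = False


@dataclass
class PlanCase:
    """One plan of the cohort (nomenclature ``Tx-yy``: toxicity grade x,
    case number yy)."""

    case_id: str
    diagnosis: str
    prescribed_dose: float  # Gy_RBE
    fraction_dose: float    # Gy_RBE
    fields: list[FieldPlan]
    toxicity_grade: int = 0
    index_flag: bool = False

    def __post_init__(self) -> None:
        n = self.prescribed_dose / self.fraction_dose
        if abs(n - round(n)) > 0.5:
            raise ValueError(
                f"{self.case_id}: prescribed/fraction dose implies a "
                f"non-integral fraction count {n:.2f}"
            )
        if not (3 <= len(self.fields) <= 4):
            raise ValueError(
                f"{self.case_id}: {len(self.fields)} fields outside 3-4"
            )

    @property
    def n_fractions(self) -> int:
        return int(round(self.prescribed_dose / self.fraction_dose))

    @property
    def n_spots(self) -> int:
        return sum(len(f.spots) for f in self.fields)

    @property
    def hot_field_id(self) -> str | None:
        for f in self.fields:
            if f.hot:
                return f.field_id
        return None


@dataclass
class CohortSpec:
    """Study conditions for the synthetic cohort (defaults emulate the
    8-case roster: prescriptions, fraction doses, grades, index cases)."""

    case_ids: tuple[str, ...] = (
        "T0-01", "T0-02", "T4-03", "T0-04", "T0-05", "T3-06", "T0-07", "T0-08",
    )
    diagnoses: tuple[str, ...] = (
        "Meningioma, WHO Grade 2", "Meningioma, WHO Grade 1",
        "Mature Teratoma", "Meningioma, unspecified",
        "Meningioma, WHO Grade 1", "Meningioma, unspecified",
        "Meningioma, WHO Grade 1", "Meningioma, WHO Grade 1",
    )
    prescribed_doses: tuple[float, ...] = (
        55.8, 50.4, 50.4, 50.4, 54.0, 50.4, 50.4, 50.4,
    )
    fraction_doses: tuple[float, ...] = (
        1.8, 1.8, 1.8, 1.8, 1.93, 1.8, 1.8, 1.8,
    )
    toxicity_grades: tuple[int, ...] = (0, 0, 4, 0, 0, 3, 0, 0)
    index_flags: tuple[bool, ...] = (
        False, False, True, False, False, True, False, False,
    )
    fields_per_case: tuple[int, ...] = (4, 3, 4, 3, 4, 3, 4, 3)  # sums to 28

    # geometry the spot maps conform to
    dims: tuple[int, int, int] = phantom.DEFAULT_DIMS
    spacing: tuple[float, float, float] = phantom.DEFAULT_SPACING
    origin: tuple[float, float, float] = phantom.DEFAULT_ORIGIN
    structure_spec: dict[str, list[Primitive]] | None = None
    target_structure: str = "CTV"
    hot_target_structure: str = "ONL"

    # planning heuristic parameters
    layer_spacing_mm: float = 2.0    # Bragg-peak depth step between layers
    spot_spacing_mm: float = 4.0     # lateral scan grid pitch
    lateral_margin_mm: float = 4.0   # margin beyond target cross-section
    field_offset_mm: float = 2.5     # per-field lateral scan-grid jitter span
    mu_jitter: float = 0.05          # relative per-spot MU noise
    rbe_constant: float = 1.1        # converts Gy_RBE prescription to Gy

    # planted high-dose-rate signal: the hot field runs at raised beam
    # current (shorter spot durations at fixed MU -> higher rates, same
    # dose), and its spots nearest the targeted optic structure carry a
    # mild MU elevation so the high-rate cloud peaks over that structure
    # without making the index cases' dose metrics atypical
    hot_factor: float = 2.5          # beam-current (rate) elevation factor
    hot_mu_factor: float = 1.5       # MU elevation of near-structure spots
    hot_radius_mm: float = 18.0      # spots peaking within this distance of
                                     # the hot target structure are elevated

    def __post_init__(self) -> None:
        n = len(self.case_ids)
        for name in ("diagnoses", "prescribed_doses", "fraction_doses",
                     "toxicity_grades", "index_flags", "fields_per_case"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have {n} entries")
        if any(not (3 <= k <= 4) for k in self.fields_per_case):
            raise ValueError("fields per case must be 3 or 4")

    def make_phantom(self) -> tuple[VoxelGrid, dict[str, StructureMask]]:
        return phantom.make_phantom(
            self.dims, self.spacing, self.structure_spec, self.origin
        )


def _target_geometry(masks: dict[str, StructureMask], name: str):
    mask = masks[name]
    idx = np.array(np.nonzero(mask.voxels)).T
    world = mask.grid.origin + idx * np.asarray(mask.grid.spacing)
    center = world.mean(axis=0)
    radius = float(np.linalg.norm(world - center, axis=1).max())
    return center, radius


def make_cohort(spec: CohortSpec | None = None, seed: int = 0,
                beam_model=None) -> list[PlanCase]:
    """Generate the synthetic cohort: one PlanCase per roster entry with
    target-conformal spot maps, MU calibrated so the fields jointly deliver
    the per-fraction prescription at the target center, and the planted
    hot-field signal on the index cases.  Bit-identical for a fixed seed.
    """
    from . import dose_engine  # deferred: dose_engine imports Spot from here

    spec = spec or CohortSpec()
    bm = beam_model or dose_engine.BeamModel()
    grid, masks = spec.make_phantom()
    t_center, t_radius = _target_geometry(masks, spec.target_structure)
    t_mask = masks[spec.target_structure]
    t_points = (np.array(np.nonzero(t_mask.voxels)).T
                * np.asarray(grid.spacing) + grid.origin)
    # reference point for "nearest the optic structure": the posterior end
    # of the nerve, i.e. the end closest to the chiasm / target
    hot_mask = masks[spec.hot_target_structure]
    hot_world = (np.array(np.nonzero(hot_mask.voxels)).T
                 * np.asarray(grid.spacing) + grid.origin)
    hot_ref = hot_world[np.argmin(np.linalg.norm(hot_world - t_center, axis=1))]

    root = np.random.SeedSequence(seed)
    case_seeds = root.spawn(len(spec.case_ids))

    cases: list[PlanCase] = []
    for c, case_id in enumerate(spec.case_ids):
        rng = np.random.default_rng(case_seeds[c])
        n_fields = spec.fields_per_case[c]
        frac_gy = spec.fraction_doses[c] / spec.rbe_constant  # physical Gy
        fields: list[FieldPlan] = []
        for k in range(n_fields):
            fid = f"{case_id}-F{k + 1}"
            spots = _field_spots(fid, grid, spec, t_center, t_radius, bm, rng)
            # calibrate MU: this field alone delivers its share of the
            # per-fraction physical dose as the mean over the target volume
            d0 = dose_engine.point_dose(
                spots, t_points, bm, entry_z=grid.entry_z
            ).mean()
            scale = (frac_gy / n_fields) / d0
            for s in spots:
                s.mu *= scale
            fields.append(FieldPlan(field_id=fid, spots=spots))
        if spec.index_flags[c]:
            hot = fields[0]
            hot.hot = True
            hot.current_scale = spec.hot_factor
            for s in hot.spots:
                peak = np.array([s.position[0], s.position[1],
                                 grid.entry_z + float(bm.range_mm(s.energy))])
                if np.linalg.norm(peak - hot_ref) <= spec.hot_radius_mm:
                    s.mu *= spec.hot_mu_factor
                    s.hot = True
        cases.append(PlanCase(
            case_id=case_id,
            diagnosis=spec.diagnoses[c],
            prescribed_dose=spec.prescribed_doses[c],
            fraction_dose=spec.fraction_doses[c],
            fields=fields,
            toxicity_grade=spec.toxicity_grades[c],
            index_flag=spec.index_flags[c],
        ))
    return cases


def _sobp_layer_weights(depths, depth_lo, depth_hi, bm):
    """Non-negative layer weights flattening the spread-out Bragg peak
    over the target depth span (least-squares, as a planning stand-in)."""
    from scipy.optimize import nnls

    z = np.linspace(depth_lo, depth_hi, 80)
    a = np.column_stack([
        bm.depth_dose(z, float(bm.energy_for_range_mm(d))) for d in depths
    ])
    w, _ = nnls(a, np.ones_like(z))
    keep = w >= 0.05 * w.max()  # deliverable-MU floor: drop negligible layers
    return w, keep


def _field_spots(field_id, grid, spec, t_center, t_radius, bm, rng):
    """Energy-layer x lateral-grid spot placement covering the target.

    Layer weights flatten the SOBP over the target depths; within a layer
    spots share the layer weight up to per-spot MU jitter.
    """
    depth_c = t_center[2] - grid.entry_z
    depths = np.arange(depth_c - t_radius + 2.0, depth_c + t_radius - 2.0 + 1e-9,
                       spec.layer_spacing_mm)
    weights, keep = _sobp_layer_weights(
        depths, depth_c - t_radius + 2.0, depth_c + t_radius - 2.0, bm)
    off = rng.uniform(-spec.field_offset_mm, spec.field_offset_mm, size=2)
    spots: list[Spot] = []
    sid = 0
    for d, w, ok in zip(depths, weights, keep):
        if not ok:
            continue
        energy = float(bm.energy_for_range_mm(d))
        energy = float(np.clip(energy, bm.energy_min_mev, bm.energy_max_mev))
        dz = d - depth_c
        r_lat = np.sqrt(max(t_radius**2 - dz**2, 0.0)) + spec.lateral_margin_mm
        n_side = int(np.ceil(2 * r_lat / spec.spot_spacing_mm)) + 1
        ax = t_center[0] + off[0] + spec.spot_spacing_mm * (
            np.arange(n_side) - (n_side - 1) / 2
        )
        ay = t_center[1] + off[1] + spec.spot_spacing_mm * (
            np.arange(n_side) - (n_side - 1) / 2
        )
        for x in ax:
            for y in ay:
                if (x - t_center[0] - off[0]) ** 2 + (
                        y - t_center[1] - off[1]) ** 2 > r_lat**2:
                    continue
                mu = w * (1.0 + spec.mu_jitter * rng.standard_normal())
                spots.append(Spot(field_id=field_id, spot_id=sid,
                                  position=(float(x), float(y)),
                                  energy=energy, mu=float(max(mu, 0.02 * w))))
                sid += 1
    return spots


# ---------------------------------------------------------------------------
# external interfaces: spot-map CSV and cohort roster JSON

def write_spot_map(case: PlanCase, path: str | Path) -> None:
    rows = [
        (f.field_id, s.spot_id, s.energy, s.position[0], s.position[1], s.mu)
        for f in case.fields for s in f.spots
    ]
    pd.DataFrame(rows, columns=SPOT_CSV_COLUMNS).to_csv(path, index=False)


def read_spot_map(path: str | Path) -> list[Spot]:
    df = pd.read_csv(path)
    missing = set(SPOT_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spot map {path}: missing columns {sorted(missing)}")
    return [
        Spot(field_id=str(r.field_id), spot_id=int(r.spot_id),
             position=(float(r.x_mm), float(r.y_mm)),
             energy=float(r.energy_mev), mu=float(r.mu))
        for r in df.itertuples()
    ]


def write_roster(cases: list[PlanCase], path: str | Path) -> None:
    roster = [
        {
            "case_id": c.case_id,
            "diagnosis": c.diagnosis,
            "prescribed_dose_gyrbe": c.prescribed_dose,
            "fraction_dose_gyrbe": c.fraction_dose,
            "n_fractions": c.n_fractions,
            "toxicity_grade": c.toxicity_grade,
            "index_flag": c.index_flag,
            "fields": [
                {"field_id": f.field_id, "n_spots": len(f.spots),
                 "current_scale": f.current_scale, "hot": f.hot}
                for f in c.fields
            ],
        }
        for c in cases
    ]
    Path(path).write_text(json.dumps(roster, indent=2))
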