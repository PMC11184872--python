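"""End-to-end cohort analysis: phantom -> plans -> doses -> logs -> metrics.

``run_cohort`` generates the synthetic cohort, computes per-spot doses and
delivery logs, and assembles the study's result surfaces: plan-level D2,
LET2, variable-RBE D2 and MDR2 per optic structure, the field-wise MDR2
table (one row per case x field x structure), cohort medians, overlay
volumes of MDR above the display threshold for the index cases' hottest
fields, and a manifest that suffices to reproduce every table value.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortSpec, PlanCase, make_cohort, write_roster
from .dose_engine import (BeamModel, accumulate_dose, accumulate_letd,
                          compute_spot_dose)
from .dose_rate import DoseRateConfig, MDRMap, compute_mdr, fieldwise_mdr2_table, near_max
from .grid import StructureMask, VoxelGrid
from .rbe import RBEModelParams, constant_rbe_dose, variable_rbe_d2
from .timing import TimingModel, synthesize_log, timing_index

logger = logging.getLogger(__name__)

OAR_NAMES = ("OC", "ONL", "ONR")
TABLE_COLUMNS = ["case_id", "field_id", "structure", "metric", "value", "units"]


@dataclass
class RunConfig:
    """Configuration of a full cohort run."""

    cohort: CohortSpec = dc_field(default_factory=CohortSpec)
    beam: BeamModel = dc_field(default_factory=BeamModel)
    timing: TimingModel = dc_field(default_factory=TimingModel)
    dose_rate: DoseRateConfig = dc_field(default_factory=DoseRateConfig)
    rbe: RBEModelParams = dc_field(default_factory=RBEModelParams)
    structures: tuple[str, ...] = OAR_NAMES
    sparse_cutoff: float = 1e-4

    def config_hash(self) -> str:
        def _plain(obj):
            if dataclasses.is_dataclass(obj):
                return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): _plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_plain(v) for v in obj]
            return repr(obj) if not isinstance(
                obj, (int, float, str, bool, type(None))) else obj
        blob = json.dumps(_plain(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class CaseResult:
    case: PlanCase
    plan_mdr: MDRMap
    field_mdr: dict[str, MDRMap]
    metrics: pd.DataFrame


@dataclass
class CohortResult:
    table: pd.DataFrame
    medians: pd.DataFrame
    manifest: dict
    cases: list[CaseResult]
    grid: VoxelGrid
    masks: dict[str, StructureMask]

    def field_rows(self, metric: str = "MDR2") -> pd.DataFrame:
        t = self.table
        return t[(t.field_id != "plan") & (t.metric == metric)]


def _analyse_case(case: PlanCase, grid, masks, config: RunConfig,
                  log_seed) -> CaseResult:
    t0 = time.perf_counter()
    spot_doses = []
    for f in case.fields:
        for s in f.spots:
            spot_doses.append(
                compute_spot_dose(s, grid, config.beam, config.sparse_cutoff)
            )
    log = synthesize_log(case.fields, config.timing, log_seed)
    timings = timing_index(log)

    dose_fx = accumulate_dose(spot_doses, grid)       # physical Gy/fraction
    letd = accumulate_letd(spot_doses)
    total_rbe = constant_rbe_dose(dose_fx, case.n_fractions,
                                  config.dose_rate.rbe_constant)

    plan_mdr = compute_mdr(spot_doses, timings, config.dose_rate, scope="plan")
    field_mdr = {
        f.field_id: compute_mdr(spot_doses, timings, config.dose_rate,
                                scope=f.field_id)
        for f in case.fields
    }

    level = config.dose_rate.percentile_level
    rows = []
    for sname in config.structures:
        mask = masks[sname]
        rows.append((case.case_id, "plan", sname, "D2",
                     near_max(total_rbe, mask, level), "Gy_RBE"))
        rows.append((case.case_id, "plan", sname, "LET2",
                     near_max(letd, mask, level), "keV/um"))
        rows.append((case.case_id, "plan", sname, "D2_varRBE",
                     variable_rbe_d2(dose_fx, letd, mask, config.rbe,
                                     case.n_fractions, level), "Gy_RBE"))
        rows.append((case.case_id, "plan", sname, "MDR2",
                     near_max(plan_mdr, mask, level), "Gy_RBE/s"))
    metrics = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    logger.info("case %s analysed in %.1f s (%d spots)", case.case_id,
                time.perf_counter() - t0, case.n_spots)
    return CaseResult(case=case, plan_mdr=plan_mdr, field_mdr=field_mdr,
                      metrics=metrics)


def run_cohort(
    config: RunConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> CohortResult:
    """Run the full cohort analysis; deterministic for a fixed seed.

    Writes (if ``out_dir`` given): ``metrics.csv``, ``field_mdr2.csv``,
    ``medians.csv``, ``roster.json``, ``manifest.json``, and per-index-case
    NIfTI overlays of the hottest field's MDR at the display threshold.
    """
    config = config or RunConfig()
    grid, masks = config.cohort.make_phantom()
    cases = make_cohort(config.cohort, seed=seed, beam_model=config.beam)
    log_root = np.random.SeedSequence([seed, 1])
    log_seeds = log_root.spawn(len(cases))

    case_results = [
        _analyse_case(case, grid, masks, config, log_seeds[i])
        for i, case in enumerate(cases)
    ]

    struct_masks = {s: masks[s] for s in config.structures}
    field_maps = {
        (cr.case.case_id, fid): fmap
        for cr in case_results for fid, fmap in cr.field_mdr.items()
    }
    field_table = fieldwise_mdr2_table(field_maps, struct_masks,
                                       config.dose_rate.percentile_level)
    table = pd.concat(
        [cr.metrics for cr in case_results] + [field_table],
        ignore_index=True,
    )
    dup = table.duplicated(subset=["case_id", "field_id", "structure", "metric"])
    if dup.any():
        raise ValueError("duplicate metric keys in table")

    plan_rows = table[table.field_id == "plan"]
    medians = (plan_rows.groupby(["structure", "metric"], as_index=False)
               ["value"].median()
               .rename(columns={"value": "median"}))

    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": config.config_hash(),
        "n_cases": len(cases),
        "n_fields": sum(len(c.fields) for c in cases),
        "n_spots": sum(c.n_spots for c in cases),
        "n_table_rows": int(len(table)),
        "n_field_mdr2_rows": int(len(field_table)),
        "index_cases": [c.case_id for c in cases if c.index_flag],
    }

    result = CohortResult(table=table, medians=medians, manifest=manifest,
                          cases=case_results, grid=grid, masks=masks)
    if out_dir is not None:
        _write_artifacts(result, cases, config, Path(out_dir))
    return result


def _write_artifacts(result: CohortResult, cases, config: RunConfig,
                     out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(out_dir / "metrics.csv", index=False)
    result.field_rows().to_csv(out_dir / "field_mdr2.csv", index=False)
    result.medians.to_csv(out_dir / "medians.csv", index=False)
    write_roster(cases, out_dir / "roster.json")
    (out_dir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2))
    for cr in result.cases:
        if not cr.case.index_flag:
            continue
        fid = hottest_field(result, cr.case.case_id)
        overlay = cr.field_mdr[fid].masked_above(
            config.dose_rate.display_threshold)
        vals = np.nan_to_num(overlay.values, nan=0.0)
        overlay.values = vals
        overlay.save(out_dir / f"overlay_mdr_{cr.case.case_id}_{fid}.nii.gz")


def hottest_field(result: CohortResult, case_id: str) -> str:
    """Field of a case with the largest field-wise MDR2 over the OARs."""
    rows = result.field_rows()
    rows = rows[rows.case_id == case_id]
    return rows.loc[rows.value.idxmax(), "field_id"]


def flag_atypical(table: pd.DataFrame, metric: str = "MDR2",
                  k: int = 2) -> list[tuple[str, str]]:
    """The k largest field-level entries for a metric, as (case, field).

    Ties are broken stably by (case_id, field_id).  k = 0 returns an empty
    list; k beyond the table returns the full ranking with a warning.
    """
    if table.empty:
        raise ValueError("metric table is empty")
    rows = table[(table.field_id != "plan") & (table.metric == metric)]
    rows = rows.sort_values(["value", "case_id", "field_id"],
                            ascending=[False, True, True])
    pairs = list(dict.fromkeys(zip(rows.case_id, rows.field_id)))
    if k > len(pairs):
        warnings.warn(f"k={k} exceeds the {len(pairs)} ranked fields; "
                      "returning the full ranking", stacklevel=2)
        k = len(pairs)
    return pairs[:k]


# ---------------------------------------------------------------------------
# YAML configuration loading for the CLI

def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file of (nested) overrides.

    Top-level keys mirror RunConfig fields (cohort, beam, timing,
    dose_rate, rbe); unknown keys raise.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    factories = {"cohort": CohortSpec, "beam": BeamModel,
                 "timing": TimingModel, "dose_rate": DoseRateConfig,
                 "rbe": RBEModelParams}
    kwargs = {}
    for key, value in raw.items():
        if key in factories:
            value = {k: tuple(v) if isinstance(v, list) else v
                     for k, v in (value or {}).items()}
            kwargs[key] = factories[key](**value)
        elif key in ("structures", "sparse_cutoff"):
            kwargs[key] = tuple(value) if isinstance(value, list) else value
        else:
            raise ValueError(f"unknown config key {key!r}")
    return RunConfig(**kwargs)
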