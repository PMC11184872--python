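"""Delivery-log time structure: parsing, synthesis, reproducibility.

The only quantity taken from a delivery log is the beam-on duration of
each spot.  Log files are a fixed CSV dialect with integer microsecond
timestamps (``field_id,spot_id,t_start_us,t_end_us``), matching the
microsecond resolution of clinical PBS log files; typical spot durations
are a few milliseconds.  Interlocks and field resumption are not modelled:
synthesized logs represent a single uninterrupted dry-run delivery.
Scanning transit between spots contributes dead time but no dose here, so
a spot's dose rate uses its beam-on duration only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import FieldPlan

LOG_CSV_COLUMNS = ["field_id", "spot_id", "t_start_us", "t_end_us"]

_SANITY_MIN_US = 100       # 0.1 ms
_SANITY_MAX_US = 100_000   # 100 ms


@dataclass(frozen=True)
class SpotTimingRecord:
    """Beam-on interval of one spot in one delivery (integer microseconds)."""

    field_id: str
    spot_id: int
    t_start_us: int
    t_end_us: int

    def __post_init__(self) -> None:
        if self.t_end_us <= self.t_start_us:
            raise ValueError(
                f"spot {self.spot_id} of field {self.field_id}: "
                f"non-monotone interval [{self.t_start_us}, {self.t_end_us}]"
            )
        if not (_SANITY_MIN_US <= self.duration_us <= _SANITY_MAX_US):
            warnings.warn(
                f"spot {self.spot_id} of field {self.field_id}: duration "
                f"{self.duration_us} us outside the typical 0.1-100 ms span",
                stacklevel=2,
            )

    @property
    def duration_us(self) -> int:
        return self.t_end_us - self.t_start_us

    @property
    def duration_s(self) -> float:
        return self.duration_us * 1e-6

    @property
    def key(self) -> tuple[str, int]:
        return (self.field_id, self.spot_id)


def parse_log(
    path: str | Path,
    expected: set[tuple[str, int]] | None = None,
) -> list[SpotTimingRecord]:
    """Read a delivery log CSV.

    If ``expected`` gives the (field_id, spot_id) keys of the referenced
    plan, every spot must be present exactly once.  Duplicate spots and
    non-monotone intervals raise with the offending spot id.
    """
    df = pd.read_csv(path)
    missing = set(LOG_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"log {path}: missing columns {sorted(missing)}")
    records: list[SpotTimingRecord] = []
    seen: set[tuple[str, int]] = set()
    for r in df.itertuples():
        key = (str(r.field_id), int(r.spot_id))
        if key in seen:
            raise ValueError(f"duplicate log record for spot {key}")
        seen.add(key)
        records.append(SpotTimingRecord(
            field_id=key[0], spot_id=key[1],
            t_start_us=int(r.t_start_us), t_end_us=int(r.t_end_us),
        ))
    if expected is not None:
        absent = expected - seen
        if absent:
            raise ValueError(f"log is missing spots: {sorted(absent)[:5]}")
        extra = seen - expected
        if extra:
            raise ValueError(f"log has unknown spots: {sorted(extra)[:5]}")
    return records


def write_log(records: list[SpotTimingRecord], path: str | Path) -> None:
    rows = [(r.field_id, r.spot_id, r.t_start_us, r.t_end_us) for r in records]
    pd.DataFrame(rows, columns=LOG_CSV_COLUMNS).to_csv(path, index=False)


@dataclass(frozen=True)
class TimingModel:
    """Spot-duration model for log synthesis.

    Nominal duration is MU divided by beam current: a spot of ``mu``
    monitor units delivered at current scale ``c`` takes
    ``mu * seconds_per_mu / c`` seconds, then a multiplicative Gaussian
    jitter of relative sigma ``jitter_sigma`` (default 0.9%, the dry-run
    spot-duration variation the generator is meant to reproduce) is
    applied.  ``dead_time_us`` separates consecutive beam-on intervals.
    """

    seconds_per_mu: float = 0.012
    jitter_sigma: float = 0.009
    dead_time_us: int = 2_000

    def __post_init__(self) -> None:
        if self.seconds_per_mu <= 0:
            raise ValueError("seconds_per_mu must be > 0")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")


def synthesize_log(
    plan_fields: list[FieldPlan],
    timing_model: TimingModel | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> list[SpotTimingRecord]:
    """Synthesize one uninterrupted delivery of the given fields.

    Within a field, beam-on intervals are ordered and non-overlapping,
    separated by the model's dead time.  Hot fields carry a raised
    ``current_scale``, so their durations stay in the typical range even
    where MU was elevated.  Seeded and reproducible.
    """
    tm = timing_model or TimingModel()
    rng = np.random.default_rng(seed)
    records: list[SpotTimingRecord] = []
    for f in plan_fields:
        if f.current_scale <= 0:
            raise ValueError(
                f"field {f.field_id}: non-positive beam current scale"
            )
        t_us = 0
        for s in f.spots:
            nominal_s = s.mu * tm.seconds_per_mu / f.current_scale
            dur_s = nominal_s * (1.0 + tm.jitter_sigma * rng.standard_normal())
            dur_us = max(int(round(dur_s * 1e6)), 1)
            records.append(SpotTimingRecord(
                field_id=f.field_id, spot_id=s.spot_id,
                t_start_us=t_us, t_end_us=t_us + dur_us,
            ))
            t_us += dur_us + tm.dead_time_us
    return records


def timing_index(
    records: list[SpotTimingRecord],
) -> dict[tuple[str, int], SpotTimingRecord]:
    """Index records by (field_id, spot_id); duplicates raise."""
    out: dict[tuple[str, int], SpotTimingRecord] = {}
    for r in records:
        if r.key in out:
            raise ValueError(f"duplicate timing record for spot {r.key}")
        out[r.key] = r
    return out


def duration_reproducibility(
    logs: list[list[SpotTimingRecord]],
) -> tuple[float, float]:
    """Spot-duration reproducibility over repeated deliveries of one field
    (or set of fields).

    For each spot, relative deviations of its duration from its per-spot
    mean are formed.  Returns ``(mean %, sd %)``: the mean absolute
    relative deviation, and the pooled (Bessel-corrected, hence unbiased
    for the underlying jitter) relative standard deviation, both in
    percent.  Identical logs give (0, 0); the statistic is scale-free.
    """
    if len(logs) < 2:
        raise ValueError("need at least 2 deliveries")
    keysets = [set(r.key for r in log) for log in logs]
    for ks in keysets[1:]:
        if ks != keysets[0]:
            raise ValueError("deliveries cover mismatched spot sets")
    keys = sorted(keysets[0])
    idx = {k: i for i, k in enumerate(keys)}
    n_rep = len(logs)
    dur = np.empty((len(keys), n_rep))
    for j, log in enumerate(logs):
        for r in log:
            dur[idx[r.key], j] = r.duration_us
    mean = dur.mean(axis=1, keepdims=True)
    rel_dev = (dur - mean) / mean
    mean_abs_pct = 100.0 * float(np.abs(rel_dev).mean())
    rel_var = dur.var(axis=1, ddof=1) / mean[:, 0] ** 2
    sd_pct = 100.0 * float(np.sqrt(rel_var.mean()))
    return mean_abs_pct, sd_pct
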