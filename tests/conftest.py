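from __future__ import annotations

import numpy as np
import pytest

from pbsmdr import (BeamModel, CohortSpec, Spot, SpotDoseSparse,
                    SpotTimingRecord, VoxelGrid, make_phantom)


@pytest.fixture(scope="session")
def beam_model():
    return BeamModel()


@pytest.fixture()
def small_grid():
    return VoxelGrid(dims=(6, 5, 8), spacing=(2.0, 2.0, 2.0),
                     origin=(-5.0, -4.0, 1.0))


@pytest.fixture(scope="session")
def default_phantom():
    return make_phantom()


def random_sparse_case(rng, grid, n_spots=8, n_fields=2, max_entries=12):
    """A random desk-scale instance: sparse spot doses plus durations.

    Doses span the 1 cGy gating threshold so valid sets are non-trivial.
    """
    spot_doses = []
    durations = {}
    for s in range(n_spots):
        fid = f"F{rng.integers(n_fields)}"
        n = int(rng.integers(1, max_entries + 1))
        idx = rng.choice(grid.n_voxels, size=n, replace=False)
        dose = rng.uniform(1e-3, 0.05, size=n)
        let = rng.uniform(0.5, 12.0, size=n)
        spot_doses.append(SpotDoseSparse(
            field_id=fid, spot_id=s, grid=grid,
            indices=idx, dose=dose, let=let,
        ))
        durations[(fid, s)] = float(rng.uniform(1e-3, 2e-2))
    return spot_doses, durations


def timing_from_durations(durations_s):
    """Build timing records (and the key->record index) from durations."""
    timings = {}
    t = 0
    for (fid, sid), dur in durations_s.items():
        dur_us = max(int(round(dur * 1e6)), 1)
        timings[(fid, sid)] = SpotTimingRecord(
            field_id=fid, spot_id=sid, t_start_us=t, t_end_us=t + dur_us)
        t += dur_us + 1000
        # recompute exact seconds after integer-us rounding
        durations_s[(fid, sid)] = dur_us * 1e-6
    return timings


def make_small_cohort_spec():
    """Three-case cohort at coarse spot sampling for fast pipeline tests."""
    return CohortSpec(
        case_ids=("T0-01", "T4-02", "T0-03"),
        diagnoses=("Meningioma", "Teratoma", "Meningioma"),
        prescribed_doses=(50.4, 50.4, 54.0),
        fraction_doses=(1.8, 1.8, 1.93),
        toxicity_grades=(0, 4, 0),
        index_flags=(False, True, False),
        fields_per_case=(3, 3, 3),
        layer_spacing_mm=4.0,
        spot_spacing_mm=7.0,
    )


def make_small_run_config():
    """RunConfig for the small cohort; faster MU-to-time scale keeps the
    coarse plan's high-MU spots inside the typical duration span."""
    from pbsmdr import RunConfig, TimingModel

    return RunConfig(cohort=make_small_cohort_spec(),
                     timing=TimingModel(seconds_per_mu=0.002))


@pytest.fixture()
def small_cohort_spec():
    return make_small_cohort_spec()


@pytest.fixture()
def simple_spot():
    return Spot(field_id="F0", spot_id=0, position=(0.0, 0.0),
                energy=100.0, mu=2.0)
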