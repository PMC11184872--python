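"""Independent brute-force reference implementations used only by tests.

Each oracle is written as directly as possible (plain loops, sorting,
closed forms) and shares no code path with the package implementation it
checks.
"""

from __future__ import annotations

import math

import numpy as np


def rasterize_bruteforce(grid, primitives):
    """Point-in-primitive test at every voxel center, one voxel at a time."""
    out = np.zeros(grid.dims, dtype=bool)
    for i in range(grid.dims[0]):
        for j in range(grid.dims[1]):
            for k in range(grid.dims[2]):
                p = np.array([
                    grid.origin[0] + i * grid.spacing[0],
                    grid.origin[1] + j * grid.spacing[1],
                    grid.origin[2] + k * grid.spacing[2],
                ])
                for prim in primitives:
                    if bool(prim.contains(p[None, :])[0]):
                        out[i, j, k] = True
                        break
    return out


def accumulate_dense(spot_doses, n_voxels):
    """Dense per-spot accumulation of dose and dose-weighted LET."""
    dose = np.zeros(n_voxels)
    dlet = np.zeros(n_voxels)
    for sd in spot_doses:
        for idx, d, l in zip(sd.indices, sd.dose, sd.let):
            dose[idx] += d
            dlet[idx] += d * l
    letd = np.full(n_voxels, np.nan)
    nz = dose > 0
    letd[nz] = dlet[nz] / dose[nz]
    return dose, letd


def mdr_exhaustive(spot_doses, durations_s, rbe, threshold, n_voxels):
    """Per-voxel max over all spot rates; validity gated by total RBE dose.

    ``durations_s`` maps (field_id, spot_id) -> seconds.
    Returns (values with NaN where invalid, valid mask), flat arrays.
    """
    best = np.zeros(n_voxels)
    total = np.zeros(n_voxels)
    for sd in spot_doses:
        t = durations_s[(sd.field_id, sd.spot_id)]
        for idx, d in zip(sd.indices, sd.dose):
            rate = rbe * d / t
            if rate > best[idx]:
                best[idx] = rate
            total[idx] += rbe * d
    valid = total >= threshold
    vals = np.where(valid, best, np.nan)
    return vals, valid


def near_max_sorted(values, level):
    """Sort-and-count near-maximum over a flat eligible-value array."""
    vals = sorted(float(v) for v in values)
    n = len(vals)
    k = max(1, math.ceil(n * level / 100.0))
    return vals[n - k]


def dose_above_rate_filter(spot_doses, durations_s, mask_flat, threshold, rbe):
    """Filter-and-sum: masked dose contributed at rate >= threshold."""
    above = 0.0
    total = 0.0
    for sd in spot_doses:
        t = durations_s[(sd.field_id, sd.spot_id)]
        for idx, d in zip(sd.indices, sd.dose):
            if not mask_flat[idx]:
                continue
            total += rbe * d
            if rbe * d / t >= threshold:
                above += rbe * d
    pct = 100.0 * above / total if total > 0 else 0.0
    return above, pct


def rbe_closed_form(d, let, alpha_beta, c0, c1, d0, d1):
    """Direct scalar evaluation of the variable-RBE closed form."""
    rmax = c0 + c1 * let / alpha_beta
    rmin = d0 + d1 * math.sqrt(alpha_beta) * let
    return (math.sqrt(alpha_beta**2 + 4 * d * alpha_beta * rmax
                      + 4 * d**2 * rmin**2) - alpha_beta) / (2 * d)
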