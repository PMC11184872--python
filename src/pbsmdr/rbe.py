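"""Structure-level dose and LET metrics: D2, LET2 and variable-RBE dose.

The variable RBE follows the phenomenological linear-quadratic model in
which the dose-response asymptotes RBE_max (D -> 0) and RBE_min (D -> inf)
are linear functions of dose-averaged LET:

    RBE_max(L) = c0 + c1 * L / (alpha/beta)
    RBE_min(L) = d0 + d1 * sqrt(alpha/beta) * L

and, per fraction dose D,

    RBE(D, L) = (sqrt((a/b)^2 + 4 D (a/b) RBE_max + 4 D^2 RBE_min^2)
                 - a/b) / (2 D).

The published fit coefficients are configuration with defaults, not
constants — the metrics are pinned to the closed form, not to a particular
fit.  For optic structures alpha/beta = 2 Gy is the default.  Note that
with the default coefficients RBE_max < RBE_min below ~0.6 keV/um at
alpha/beta = 2; this is a property of the fit, not an error, and the
closed form remains well defined there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dose_rate import near_max
from .grid import ScalarMap, StructureMask, same_grid


@dataclass(frozen=True)
class RBEModelParams:
    """Phenomenological variable-RBE model parameters (see module docs)."""

    alpha_beta: float = 2.0            # Gy
    rbe_max_intercept: float = 0.99064
    rbe_max_slope: float = 0.35605     # per (keV/um)/Gy : multiplies L/(a/b)
    rbe_min_intercept: float = 1.1012
    rbe_min_slope: float = -0.0038703  # per (keV/um)*Gy^-1/2 : multiplies sqrt(a/b)*L
    let_span: tuple[float, float] = (0.0, 20.0)

    def __post_init__(self) -> None:
        if self.alpha_beta <= 0:
            raise ValueError("alpha_beta must be > 0")
        lets = np.linspace(*self.let_span, 200)
        if np.any(self.rbe_max(lets) <= 0) or np.any(self.rbe_min(lets) <= 0):
            raise ValueError(
                "RBE_max/RBE_min must be positive over the LET span"
            )

    def rbe_max(self, let) -> np.ndarray:
        let = np.asarray(let, dtype=float)
        return self.rbe_max_intercept + self.rbe_max_slope * let / self.alpha_beta

    def rbe_min(self, let) -> np.ndarray:
        let = np.asarray(let, dtype=float)
        return (self.rbe_min_intercept
                + self.rbe_min_slope * np.sqrt(self.alpha_beta) * let)


#: Degenerate configuration that reduces the variable model to constant 1.1.
CONSTANT_11_PARAMS = RBEModelParams(
    rbe_max_intercept=1.1, rbe_max_slope=0.0,
    rbe_min_intercept=1.1, rbe_min_slope=0.0,
)


def mcnamara_rbe(
    dose_per_fraction,
    letd,
    params: RBEModelParams | None = None,
) -> np.ndarray:
    """Variable RBE at given per-fraction dose (Gy) and LET_d (keV/um).

    Vectorized; raises on non-positive dose.  RBE -> RBE_min(L) as
    D -> inf and grows toward RBE-max-dominated values as D -> 0+.
    """
    p = params or RBEModelParams()
    d = np.asarray(dose_per_fraction, dtype=float)
    let = np.asarray(letd, dtype=float)
    if np.any(d <= 0):
        raise ValueError("dose_per_fraction must be > 0")
    ab = p.alpha_beta
    rmax = p.rbe_max(let)
    rmin = p.rbe_min(let)
    disc = ab**2 + 4.0 * d * ab * rmax + 4.0 * d**2 * rmin**2
    assert np.all(disc >= 0), "discriminant negative: invalid RBE parameters"
    out = (np.sqrt(disc) - ab) / (2.0 * d)
    return out if out.ndim else float(out)


def constant_rbe_dose(
    physical_dose_map: ScalarMap,
    n_fractions: int = 1,
    rbe_constant: float = 1.1,
) -> ScalarMap:
    """Total RBE-weighted dose map under a constant RBE."""
    return ScalarMap(
        physical_dose_map.grid,
        rbe_constant * n_fractions * physical_dose_map.values,
        units="Gy_RBE", name="dose_rbe_const",
    )


def variable_rbe_dose(
    physical_dose_map: ScalarMap,
    letd_map: ScalarMap,
    params: RBEModelParams | None = None,
    n_fractions: int = 1,
    per_fraction: bool = True,
) -> ScalarMap:
    """Total variable-RBE-weighted dose map.

    The RBE is evaluated at the per-fraction dose (default, matching
    fractionated delivery) or, with ``per_fraction=False``, at the total
    physical dose; either way it scales the total physical dose.  Voxels
    with zero dose get zero RBE dose; voxels with dose but undefined LET_d
    cannot occur by construction (LET_d is defined wherever dose is).
    """
    if not same_grid(physical_dose_map.grid, letd_map.grid):
        raise ValueError("dose and LET_d maps are on different grids")
    p = params or RBEModelParams()
    d_fx = physical_dose_map.values
    pos = d_fx > 0
    rbe = np.ones_like(d_fx)
    d_eval = d_fx if per_fraction else n_fractions * d_fx
    rbe[pos] = mcnamara_rbe(d_eval[pos], letd_map.values[pos], p)
    total = n_fractions * d_fx * rbe
    return ScalarMap(physical_dose_map.grid, total, units="Gy_RBE",
                     name="dose_rbe_var")


def d2(dose_map: ScalarMap, mask: StructureMask, level: float = 2.0) -> float:
    """DVH near-maximum dose: value received by ``level``% of the volume."""
    return near_max(dose_map, mask, level)


def let2(letd_map: ScalarMap, mask: StructureMask, level: float = 2.0) -> float:
    """Near-maximum LET_d over a structure.

    Only voxels where LET_d is defined (i.e. received dose) are eligible;
    a structure with no dosed voxels raises.
    """
    return near_max(letd_map, mask, level)


def variable_rbe_d2(
    physical_dose_map: ScalarMap,
    letd_map: ScalarMap,
    mask: StructureMask,
    params: RBEModelParams | None = None,
    n_fractions: int = 1,
    level: float = 2.0,
    per_fraction: bool = True,
) -> float:
    """Near-maximum of the variable-RBE-weighted total dose."""
    vmap = variable_rbe_dose(physical_dose_map, letd_map, params,
                             n_fractions, per_fraction)
    return near_max(vmap, mask, level)
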