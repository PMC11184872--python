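# Methods

## Scope and data model

The package analyses PBS proton plans at the resolution the question
requires: per spot and per voxel. All maps live on a shared `VoxelGrid`
(voxel indices 0-based; world coordinates are voxel-center positions in mm;
capped at 2·10^6 voxels for desk-scale runs). Structure masks are binary —
a voxel belongs to a structure iff its center lies inside one of the
structure's geometric primitives — and structure volume is voxel count
times voxel volume. No partial-volume weighting is applied anywhere, so
every percentile-type metric is exactly reproducible by counting voxels.

A spot's dose contribution is stored sparsely as `(voxel index, dose, LET)`
records (`SpotDoseSparse`); everything downstream — accumulation, LET_d,
dose rates, MDR — consumes only this contract. A Monte Carlo engine could
replace the analytic engine without touching any metric.

## Analytic pencil-beam engine

The engine is a deliberately simple stand-in whose purpose is to produce
per-spot dose/LET grids with the right qualitative structure; it is not
commissioned for clinical use.

* **Range:** Bragg–Kleeman, `R = a·E^p` with `a = 0.0022 cm/MeV^p`,
  `p = 1.77` (water), commissioned span 70–230 MeV.
* **Depth dose:** an entrance plateau rising mildly toward the peak
  (fractional rise 0.4) that switches off over the distal falloff, plus a
  Gaussian Bragg peak centered at the nominal range with a configurable
  peak-to-entrance ratio (default 3.5). The peak width
  `sigma = 0.024·R^0.935 cm` is wider than pure range straggling
  (~0.012·R^0.935) to absorb beamline energy spread; with the default
  2 mm energy-layer step this keeps the spread-out Bragg peak smooth.
* **Lateral profile:** a 2-D Gaussian with
  `sigma(z) = sqrt(sigma_air^2 + (0.03 z)^2)`, `sigma_air = 3 mm`.
* **LET:** the stopping power implied by the range–energy rule, evaluated
  at the local residual range, regularized 0.2 mm before track end and
  clipped to 0.2–20 keV/µm. It is monotone non-increasing in residual
  range. Secondary particles are not modelled; real dose-averaged LET
  (which includes secondary protons, deuterons, alphas) differs mainly in
  the entrance region.
* **Units:** `dose_per_mu` (default 1 Gy·mm² per MU) converts monitor
  units to laterally integrated dose; dose is linear in MU.
* **Sparse cutoff:** per-spot entries below 10^-4 Gy are dropped. This is
  storage economy only and is distinct from the 1 cGy metric threshold.

Model invariants (range monotone in energy, non-negative single-peak depth
dose, non-decreasing lateral sigma, monotone bounded LET) are validated
programmatically.

## Delivery-time model

Only the beam-on duration of each spot is used; scanning transit and dead
time contribute no dose and the dose rate of a spot is its dose divided by
its beam-on duration. Logs are CSV with integer microsecond timestamps.
Synthesized durations are `mu · seconds_per_mu / current_scale` (default
12 ms/MU, giving a ~4 ms median spot for the default cohort) with
multiplicative Gaussian jitter of 0.9%, the dry-run reproducibility level
the generator is meant to emulate. Interlocks and field resumption are not
modelled: every synthetic log represents one uninterrupted delivery.

The reproducibility statistic over repeated deliveries returns the mean
absolute relative deviation of spot durations from their per-spot means,
and the pooled Bessel-corrected relative SD (unbiased for the generator's
jitter sigma, which a naive n-denominator pooled SD would underestimate by
~10% at 5 repeats).

## MDR and near-maximum metrics

`MDR(v) = max_s rbe · d_s(v) / t_s` over the spots in scope (plan or one
field). The voxel validity gate defaults to **total-dose gating**: a voxel
enters the map iff its total per-fraction RBE-weighted dose is at least
`dose_threshold` (default 0.01 Gy = 1 cGy). A per-spot-contribution gate is
available behind `gate_mode="per_spot"`. MDR absolute values are sensitive
to this threshold, which is why it is explicit configuration. Consequence
of per-scope gating: the plan map equals the voxelwise max of its field
maps on the *common* valid set (voxels valid in every field map); a voxel
can clear the plan-level gate while sub-threshold in the field owning its
fastest spot.

`near_max(map, mask, level)` is the single percentile routine behind D2,
LET2, MDR2 and variable-RBE D2: the smallest value `m` such that at least
`level`% of the eligible structure volume has value ≥ m. Over discrete
voxels this is the k-th largest eligible value with
`k = ceil(n·level/100)`; ties at the boundary are included by construction,
`level → 0+` gives the masked maximum and `level = 100` the masked
minimum. Eligibility: valid voxels for MDR maps, defined (non-NaN) voxels
for LET_d, all masked voxels for dose.

`dose_above_dose_rate` sums, over masked voxels, only the spot
contributions delivered at or above a rate threshold, and reports the sum
and its percentage of total masked dose. It is monotone non-increasing in
the threshold.

The overlay export masks MDR below a display threshold (default
3 Gy_RBE/s); it is presentation only and never enters metric values.

## Variable RBE

`RBE_max(L) = 0.99064 + 0.35605·L/(a/b)` and
`RBE_min(L) = 1.1012 − 0.0038703·sqrt(a/b)·L` feed the linear-quadratic
closed form given in the README; `a/b = 2 Gy` by default for optic
structures. The coefficients are configuration, not constants: the metrics
are pinned to the closed form. Two numerical notes: (i) with these
coefficients `RBE_max < RBE_min` below ~0.6 keV/µm at `a/b = 2`; this is a
property of the published fit, the closed form remains well defined, and
validation therefore checks positivity of both lines rather than their
ordering; (ii) the RBE is evaluated at the **per-fraction** dose by default
(the cohort delivers ~1.8 Gy_RBE fractions) and scales the total physical
dose — evaluation at total dose is available behind `per_fraction=False`,
since either reading is defensible. A degenerate parameterization
(intercepts 1.1, slopes 0) reduces the model exactly to constant RBE 1.1
and is exposed as `CONSTANT_11_PARAMS`.

## Synthetic cohort: what it emulates and what it does not

The default cohort reproduces the roster-level study conditions: 8
intracranial cases (prescriptions 55.8, 50.4, 50.4, 50.4, 54, 50.4, 50.4,
50.4 Gy_RBE; fraction doses 1.8 except 1.93 for the 54 Gy_RBE case), 3–4
fields per plan, 28 fields total, two index cases (T4-03, T3-06) with
toxicity grades 4 and 3. The phantom is geometric: OC a 4 mm-radius
sphere, ONL/ONR 2.5 mm-radius tubes running anteriorly, CTV a 12 mm-radius
sphere abutting the chiasm; all on a 40×40×60 grid at 2 mm.

Spot maps are target-conformal in a simple sense: energy layers step the
Bragg peak through the CTV at 2 mm; layer weights are the non-negative
least-squares solution flattening the spread-out Bragg peak over the
target depths, with a 5%-of-max deliverable-MU floor; each layer carries a
4 mm lateral spot grid covering the target cross-section plus margin, with
a per-field scan-grid offset and 5% per-spot MU jitter. MU is calibrated
per field so the fields jointly deliver the per-fraction prescription as
the mean over the CTV. This is a planning stand-in — no optimizer, no OAR
sparing objectives, all fields along one axis — so absolute OAR doses are
only prescription-scale plausible, not clinically representative.

The planted high-dose-rate signal follows the premise that high MDR comes
from delivery-time structure rather than dose: each index case's first
field runs at 2.5× beam current (spot durations ÷2.5 at fixed MU, so every
rate in the field rises 2.5× while dose is unchanged), and that field's
spots whose Bragg peaks fall within 18 mm of the left optic nerve
additionally carry a mild 1.5× MU elevation so the high-rate cloud peaks
over the nerve. With these defaults the control plans' optic-structure
MDR2 sits around 2.5–4 Gy_RBE/s and the index plans around 8–10, so the
two hot fields are the two largest of the 84 field-level values — the same
qualitative picture the metrics are designed to surface — while the index
cases' D2 stays within the cohort's normal range. Passing recovery tests
on this cohort show the metric chain orders and localizes a planted
delivery-time signal correctly; they say nothing about clinical plan
realism, tissue heterogeneity, or actual toxicity risk.

## Numerical and design choices

* Seeds are explicit everywhere; per-case and per-log seeds are spawned
  from the user seed via `numpy.random.SeedSequence`, so cohorts are
  bit-identical under a fixed seed and independent of evaluation order.
* Per-fraction basis throughout: spot doses are per fraction, so dose
  rates are fraction-count independent; total-dose metrics multiply by the
  fraction count (prescribed/fraction dose rounded to the nearest
  integer, required within 0.5).
* Degenerate inputs fail loudly: empty structures, missing/duplicate log
  records, non-monotone intervals, energies outside the commissioned span,
  mixed grids, empty MDR scopes and empty eligible sets all raise with the
  offending identifier. A beam that misses the grid yields an empty sparse
  set with a logged warning (a geometric miss is data, not a bug).
* Spot durations outside 0.1–100 ms warn but do not fail (sanity span
  around the "several ms" typical scale).
* NIfTI is the only volumetric exchange format (affine = diagonal spacing
  + origin); metric tables are CSV with one row per
  (case, field-or-plan, structure, metric).

## Problem sizes

Defaults are desk-scale by construction: 96k voxels, ~10.7k spots across
28 fields, one full cohort analysis in roughly 10 s and the whole test
suite in well under a minute on one core. The structure of the analysis is
unchanged at clinical grid sizes; only the engine and grid resolution
would scale up.

## Known limitations

* The analytic engine ignores tissue heterogeneity, nuclear halo, range
  straggling through real anatomy, and secondary-particle LET.
* The planner heuristic has no OAR objectives and one beam direction per
  cohort; field-wise variation comes from scan-grid offsets and MU jitter
  only.
* Time-window-averaged dose rates (e.g. 100 ms windows) and dose-rate
  thresholding semantics other than the two implemented gates are out of
  scope.
* The per-structure vs pooled reading of "2% of the volume of any of the
  three structures" is ambiguous in the source analysis; this package
  reports per-structure values (the table contains every structure, so a
  max-over-structures pooled value is a one-line aggregation away).
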