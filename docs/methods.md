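# Methods

## Scope and intent

`mlcsim` implements a step-function model of transmission through a
rounded-leaf-end MLC, a deliberately simple planar dose engine, 2D gamma
analysis, and the sequential commissioning workflow that derives the MLC
parameters from measurements. All measurements are synthetic, generated from
a known machine truth, so the package's claims are about *parameter
recovery under stated noise*, not about any physical machine.

## Coordinate conventions

Leaf travel is along `x`, the cross-leaf axis is `y`; everything is
projected to the isocenter plane and expressed in cm. A rectangular field
specification `(X1, X2)` places the A-bank (left) leaf ends at `−X1` and the
B-bank ends at `+X2`; a negative entry means that bank travels across the
central axis, so `(15, −5)` spans `x ∈ [−15, −5]`. Jaw settings follow the
same sign convention. Percent quantities are stored as fractions internally
and rendered as percent in reports.

## The MLC transmission model

For a single leaf pair with end positions `(a, b)`:

* tip positions: `tip_A = a + m(a)`, `tip_B = b − m(b)`, where
  `m(x) = offset + gain·x + curvature·x²` is the fitted vendor-table offset
  magnitude. The magnitude is applied *toward the field opening* in each
  bank's local sense; `evaluate_tip_position` by itself evaluates the
  polynomial in the machine coordinate exactly as the vendor table tabulates
  it. Overtraveled leaves use the same even-dominated polynomial; the
  default machine truth (`m(x) = 0.0008·x²`, 0 at the axis, 0.32 cm at
  ±20 cm) is symmetric, so the bank-local sign question is moot for it.
* transmission: 1 strictly between the tips; `√T` in the band of width
  `w_tip` on the blocked side of each tip (`[tip_A − w_tip, tip_A]`, mirror
  for B); `T` elsewhere under the leaf. The band belongs to the leaf — the
  rounded end is modeled as half the leaf thickness — so it never extends
  into the open field. Half-open interval logic puts the tip position itself
  in the band, so an abutted pair exposes no fully open point and a closed
  junction shows a `2·w_tip`-wide `√T` stripe (real plans park junctions
  under jaws, where jaw transmission — default 0 — dominates).
* tongue-and-groove: `√T` bands of width `w_TG` inside the open region along
  a cross-leaf boundary, only where that pair is open at `x` while the
  neighboring pair's leaf covers `x` (aperture periphery). No band is added
  when the neighbor's opposing leaf ends are closed on each other, and none
  arises where both pairs share the opening. Where a tongue-and-groove band
  overlaps a tip band the smaller transmission wins.
* interleaf/intraleaf leakage beyond the single average `T` is not modeled,
  and jaw leakage defaults to zero (both configurable).

### Rasterization

`compute_segment_fluence` rasterizes by exact per-cell area averaging: the
piecewise-constant transmission is integrated analytically over each cell in
`x`, band coverage is fractional in `y`, and jaw shielding is area-weighted
per axis. This matters because the default grid (2 mm, the typical energy-
fluence resolution of the modeled TPS class) is coarser than the 0.5–1 mm
tongue-and-groove bands and comparable to the tip bands: point sampling
would quantize their effect to whole cells and destroy the graded, monotone
response the commissioning search relies on. The point evaluator
`point_transmission` retains the pure step-function semantics.

Fluence is affine in `(1, T, √T)` once the band widths are fixed; the
transmission grid search exploits this by convolving three component maps
per plan and forming each candidate as a linear combination. This is exact,
not an approximation.

## Dose engine

A normalized isotropic two-Gaussian pencil kernel,
`k = (1−w)·G(σ_p) + w·G(σ_s)`, applied by separable convolution with
edge-replicated padding. Defaults `σ_p = 0.3 cm`, `σ_s = 2.0 cm`,
`w = 0.12` give an open-field 20–80% penumbra of ≈ 0.6 cm and output
factors that fall monotonically with MLC field size — the phenomenology
needed by the workflow, with no claim of matching any machine. There is a
single dmax-like plane: no depth dose, no spectral or energy distinction
(the commissioning literature for this model class reports identical MLC
parameters across photon energies, and the package follows that by having
one generic beam). Out-of-field tail accuracy of real beam models (the
few-percent-of-CAX constraint clinical commissioning imposes) is *not*
emulated by this kernel; conclusions about tail-driven effects should not be
drawn from it. Profiles within `2σ_s` of the grid boundary are affected by
padding; grids are sized with margins so commissioning never reads them.

Output factors are central-axis dose ratios against a 10×10 cm reference
aperture on a shared grid. With the default kernel they reproduce the
qualitative small-field ordering (OF falls through 6, 4, 3, 2 cm) and the
greater tip-position sensitivity of the smallest fields, which is what the
invariant tests assert — the numerical values are kernel-dependent.

## Gamma analysis

`gamma_map(reference, evaluated, criteria)` treats the *reference* as the
measurement. The evaluated distribution is resampled bilinearly on a 0.5 mm
lattice anchored at each reference point; the dose tolerance is a percent of
the reference maximum (global) or of the local reference dose (local); the
threshold mask (default 10% of the reference maximum) is computed on the
reference only. The search runs over a disc of radius `3·dta` and then
expands exactly: any point whose current best γ exceeds `radius/dta` is
re-searched at radius `γ·dta`, since beyond that distance the spatial term
alone exceeds the current best. The reported γ is therefore the true lattice
minimum, not a truncated bound. A point passes when `γ ≤ 1 + 1e−9`; the
guard absorbs float representation error so that a dose shift exactly equal
to the tolerance (γ = 1 analytically) counts as a pass, as the boundary
definition requires.

`brute_force_gamma` is an independent oracle: it refines the evaluated grid
ten-fold and minimizes exhaustively (with the same lossless distance bound
used for pruning only), refusing reference grids beyond 50×50. The
acceptance suite demands agreement with `gamma_map` to 1e−3 in γ at every
evaluable point; in practice agreement is at machine precision because both
searches operate on the same 0.5 mm lattice.

## Commissioning workflow

Stages run in order of decreasing independence, each consuming prior
selections:

1. **Offset polynomial** — ordinary least squares on the 41-row vendor-style
   table, with R² reported.
2. **Leaf-tip width** — candidates {0.1, 0.2, 0.3, 0.4} cm, scored against
   the six MLC-defined profile fields ((15,−5), (7.5,7.5), (18,0), (5,5),
   (−3,10), (−10,15); 40 cm cross-leaf extent). The primary key is mean
   |ΔFWHM| — FWHM depends on the tip width only, which decouples this stage
   from the still-unknown transmission — with mean penumbra RMSE breaking
   ties. Transmission and T&G must be fixed to *something* here; the package
   uses the median transmission candidate and the smallest T&G candidate,
   which the FWHM key renders immaterial.
3. **Average transmission** — candidates {1.6, 1.8, 2.0, 2.5, 3.0}%, scored
   by the mean 2%/2 mm global passing rate over the QA plans (the stricter
   criterion spreads the candidates far more than 3%/3 mm, which is computed
   and reported alongside). Among candidates within `tie_tolerance`
   (0.5 pp) of the best mean, the *lowest* transmission wins — codifying the
   preference for values closer to published leaf-leakage measurements when
   the data cannot discriminate.
4. **Tongue-and-groove width** — candidates {0.05, 0.1} cm, same objective;
   ties break to the smallest width (the physically smaller choice when no
   difference is seen).

The printed candidate grids are searched exhaustively; with four or five
candidates per stage there is nothing to gain from continuous optimization,
and tie-breaking is deterministic and seed-independent. All plan doses are
computed gantry-collapsed (every beam at 0°), matching planar-QA
measurement practice; no couch or gantry machinery exists.

## Synthetic data

`MachineTruth` defaults to curvature 0.0008 /cm, tip width 0.3 cm,
transmission 2.5%, T&G 0.05 cm, 1% multiplicative measurement noise and
0.2 cm chamber blur. Generators are pure functions of (parameters, seed):

* **Vendor table** — 41 rows, noise-free by default in the packaged dataset
  (it emulates a digital vendor file, not a measurement); Gaussian noise is
  available for Monte-Carlo studies of the fit.
* **Profile scans** — engine dose on a narrow slab, blurred by a 0.2 cm
  Gaussian (emulating a 4 mm-diameter scanning chamber), sampled at 1 mm,
  with multiplicative noise and a 0.1%-of-max additive floor.
* **Planar QA** — gantry-collapsed composite dose sampled on a regular
  0.5 cm, 26×26 cm diode grid, scaled by a per-session calibration factor
  ~N(1, 0.3%) emulating daily-output normalization, plus noise. Real diode
  arrays use a denser diagonal-offset layout; the regular grid simplifies
  alignment and is configurable, so array-geometry effects are out of scope.
* **Plans** — random step-and-shoot plans: per segment, a random-walk strip
  of 0.5–4 cm per leaf pair inside a 12 cm field, random MU in [2, 10],
  6–14 beams and 25–50 segments per plan (clinical step-and-shoot
  statistics). The resulting composites are modulated enough that the
  transmission stage discriminates between neighboring candidates.

Because measurement and calculation share the same engine, noise-free
datasets close the loop exactly; what passing tests demonstrate is the
correctness and discriminating power of the *workflow*, not the fidelity of
the dose engine to a real beam. Features of real data deliberately absent:
detector angular response, array geometry, beam-model/tail mismatch,
inter-energy differences, setup error beyond the rigid shifts used in the
gamma-oracle map pairs.

## Problem sizes and runtime choices

The test suite runs 20 commissioning replicates (seeds 0–19) for the
recovery property, 20 seeded 30×30 map pairs for the oracle equivalence,
and 50 pairs for the gamma ordering properties; `scripts/acceptance.py`
reports a 10-replicate recovery rate. These sizes keep the whole suite
within a few minutes on one CPU while leaving the binomial statistics
meaningful.

## Known limitations

* The transmission response around the truth is nearly symmetric (the only
  asymmetry is the √T band term), so when the truth sits exactly on an
  interior grid point the passing-rate column falls on *both* sides of it;
  a plateau extending to the next-higher candidate — as clinic data can
  show when the effective leakage lies between two candidates — appears
  only partially, and the 2.5→3.0% drop at the packaged conditions is
  ≈ 0.6–0.9 pp, just outside the 0.5 pp tie band.
* The lowest-within-tolerance tie rule can select the candidate below the
  truth on occasional noise draws when the column saturates; at the
  packaged noise level this costs roughly one replicate in twenty.
* The dose engine is phenomenological; absolute dosimetry, depth dose,
  heterogeneity and 3D effects are out of scope, as are DICOM-RT and native
  measurement-file formats (plain JSON/CSV interchange only).
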