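# Methods

## Model and assumptions

The package models a bacterial cell envelope in contact with a square
lattice of rigid nanopillars topped by spherical caps. Assumptions, in
decreasing order of importance:

* **Thin-sheet linear elasticity.** The envelope is a homogeneous,
  isotropic, linear-elastic sheet with area-stretch stiffness `k`
  (`T = kE`). This is appropriate for non-growing (stationary-phase) cells
  on timescales short against growth; viscoelastic stress relaxation,
  anisotropy and strain stiffening are ignored.
* **Isotropic tension.** Minimizing the free-energy functional under these
  assumptions makes the tension tensor isotropic, `T(x) = τ(x)I`, and
  piecewise constant: `τ_B = kλ` over the suspended region and
  `τ_A = kλ − ε′` over the adhering region.
* **Geometry family.** One cap per `d × d` unit cell; the envelope wets the
  cap as a spherical patch up to a wetting angle `θ` and is flat over the
  gaps (the curvature of the suspended membrane is neglected). `θ` is
  capped at `θ_max = arcsin(ρ/R)`: the cap rim has a tiny local radius of
  curvature, and its bending energy (`∝ κρ/r_edge`) exceeds the cap's
  (`∝ κ(ρ/R)²`) by the ratio `R²/(ρ·r_edge)` — two or more orders of
  magnitude for nanometre-scale rims — so the envelope never wraps past
  the rim. The rim itself carries no explicit energy term; its only role
  is the `θ_max` bound.
* **Effective adhesion.** Constant adhesion energy density `ε` wherever
  envelope touches cap, reduced by the Helfrich bending cost of the
  spherical patch: `ε′(R) = ε − 2κ/R²`. `ε′ ≤ 0` means no adhesion and an
  undeformed envelope — a valid outcome, not an error.
* **Per-cell reference area.** The area constraint uses `S0 = d²` per unit
  cell: an initially flat, unstrained envelope patch spanning one lattice
  cell, which makes `θ = 0, λ = 0, F = 0` the exact reference state. A
  whole-cell (global) `S0` would couple cells and is not representable in
  the single-cell reduction.

A consequence worth knowing: differentiating `F` along the constraint gives
`dF/dθ = A'(θ)[(λ−e)/(λ+1−e) − cosθ·λ/(λ+1)]` with `e = ε′/k`, so every
*interior* free-energy minimum has `λ > e`, i.e. the adhering region
carries a small positive tension, not compression; compression of the
contact zone (`τ_A < 0`) arises only in strong-adhesion/boundary regimes.
Relatedly, flattening the cap (`R/ρ → ∞` at fixed `ρ`) does **not** send
the suspended tension to zero: adhesion compresses the contact disc and the
released area tensions the gaps, so `τ_B` plateaus at `ε′·π(ρ/d)²`. Truly
negligible flat-cap tensions therefore require edge-suppressed adhesion,
which is how flat-topped pillars are modelled (below).

## Parameters

| parameter | meaning | unit | default / typical |
|---|---|---|---|
| `R` | cap radius of curvature | nm | 40–50 (CS caps); `200ρ` for flat tips |
| `ρ` | cap radius | nm | 17.5–42 |
| `d` | lattice pitch | nm | 90 (86 effective when caps cluster) |
| `k` | envelope stretch stiffness | mN/m | box 700–2500 |
| `ε` | adhesion energy density | mN/m | box 0.3–1.0 |
| `κ` | bending rigidity | J | box 1e-20–1e-19 |

The default envelope box (`DEFAULT_ENVELOPE_BOX`) represents stiff
(gram-positive-like) envelopes: `k` from a wall Young's modulus of tens of
MPa times a 20–30 nm wall, weak nonspecific adhesion of 0.3–1 mJ/m², and
bending rigidities of a few to tens of kT. Users studying a specific
organism should supply their own box; every interval-producing function
takes one.

Dimensionless groups used throughout: `R/ρ`, `ρ/d`, `ε′/k`, and the
bending parameter `a = 2κ/(k·d²)` — the unique dimensionless combination of
`κ`, `k` and the lattice scale. The solver works in units of `d` (lengths)
and `k` (energy per area); thin wrappers convert to nm and mN/m.

## Numerics

* **Constraint root.** The area constraint's right side is strictly
  decreasing in `λ` on the admissible interval `λ > max(−1, −1+e)` and
  diverges at its lower end, so the root is unique; it is bracketed
  (geometric expansion of the upper bound) and solved with Brent's method
  to machine precision. At `θ = 0` the closed form `λ = sqrt(A_sus/S0) − 1`
  is used. Returned states carry a relative constraint residual, asserted
  ≤ 1e-9 by the tests.
* **Wetting-angle minimization.** Bounded scalar minimization of
  `F(θ, λ(θ))` on `[0, θ_max]` (tolerance 1e-8 rad) with both endpoints
  checked; ties are broken toward the smallest `θ`. Cross-checked against
  a dense 10⁴-point grid oracle with an independent bisection root-finder
  on 100 seeded random parameter draws.
* **Design search.** `optimize_design` maximizes `τ_B/k` with a
  boundary-included grid over `ρ/d` (10 points by default), a 48-point
  coarse grid plus bounded refinement over `R/ρ`, and a final local
  refinement of `ρ/d`. Deterministic; doubling grid resolution moves the
  optimum by < 0.01 in `R/ρ`.
* **Interval propagation.** `tension_interval` evaluates a deterministic
  grid over the `(k, ε, κ)` box (16 points per non-degenerate axis by
  default) and refines both endpoints with Nelder–Mead in unit-cube
  coordinates; `τ_B` is smooth but non-monotone in `κ` (through `ε′` and
  `θ*`), which is why plain interval arithmetic is not used. An entirely
  non-adhesive box yields `[0, 0]` with a warning.
* **Degenerate inputs.** Tightly packed hemispheres (`R = ρ = d/2`,
  `θ_max = π/2`) are admissible — the suspended area stays positive since
  `1 − π/4 > 0`. States at or below the collapse bound `τ = −k` raise
  errors rather than returning unphysical values.

## Flat-topped pillars

Flat tips are represented inside the spherical-cap family as near-flat caps
(`R/ρ = 200`, sagitta ≈ 0.04 nm on a 35 nm cap) whose adhesion is
suppressed by the sharp-edge bending penalty, `ε → 10⁻⁴·ε` by default.
The suppression constant is a modelling choice, not a measured quantity:
the physical statement is only that edge bending makes flat tops nearly
non-adhesive. Under the default box this puts flat-cap tensions three to
four orders of magnitude below spherical-cap ones — the qualitative
prediction that flat-topped pillars are not bactericidal.

## Assay statistics

Viable fraction = mean dilution-corrected surface CFU / mean
dilution-corrected control CFU, computed per replicate so that group
comparisons operate on per-replicate fractions. The two-group comparison
is an unpaired two-tailed Student (pooled-variance) t-test — the common
reading of "parametric t-test" in plate-count work — with Welch available
via `test="welch"`. Two zero-variance groups with equal means return
p = 1 by convention. Killing rate = `N0·(1−f)/(t·A)` in cells·h⁻¹·cm⁻²;
`f > 1` (net growth) warns and returns a negative rate.

## Synthetic data

`generate_sem_lattice` emulates top-view SEM measurements: square-lattice
positions with isotropic Gaussian jitter, Gaussian cap-diameter measurement
noise, and optional pairwise clustering (adjacent column pairs drawn
together, default 4 nm total, turning a 90 nm lattice into an 86 nm
effective pitch) mimicking the capillary pairing of flexible pillars.
`generate_assay_counts` draws control wells from `Poisson(N)` and surface
wells from `Poisson(f·N)` with `N = 200` (a mid-range countable plate) —
pure Poisson plating noise, no overdispersion.

What this does *not* emulate: real SEM images (no pixels, no segmentation
errors), correlated plating errors, dilution-series error propagation,
biological replicate-to-replicate variability beyond Poisson, or partial
clustering into larger domains. Passing tests therefore validate the
estimators against idealized measurement noise, not against instrument
systematics.

The geometry estimator reports the *effective* pitch as a bias-corrected
mean nearest-neighbour distance. On a jittered lattice the NN distance is
a minimum over four neighbour distances and is biased low; Monte-Carlo
calibration of that minimum (with the neighbour correlations of the square
lattice) gives bias = 1.7029 × sd(NN), which is added back. The correction
vanishes for noiseless or purely clustered samples, so those recover the
pitch exactly. Reported standard errors combine a seeded bootstrap with a
0.5% multiplicative calibration floor, reflecting SEM magnification
calibration uncertainty, which dominates the statistical error for
hundreds of pillars. The cap's radius of curvature is not identifiable
from a top view; it is taken from an optional side-view (chord, height)
profile via the sagitta relation, or defaults to hemispherical `R = ρ`.

## Known limitations

* Single-unit-cell reduction: no cell-scale curvature, no coupling between
  cells, no finite cell size.
* Rigid pillars: cap clustering is handled only as a reduced effective
  pitch, not as strain relaxation by pillar bending.
* Quasi-static adhesion: no adhesion kinetics, EPS effects, or rupture
  kinetics; the verdict is a static comparison of tension intervals
  against a literature window (default 30–75 mN/m, overridable).
* The edge-suppression constant for flat tips and the envelope-parameter
  box are declared defaults, not fitted quantities; conclusions that
  depend on them should be re-run with user-supplied values.
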