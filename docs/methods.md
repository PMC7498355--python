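# Methods

## Model

Apl binding on the pR-pL region is treated as equilibrium occupancy of a 1-D
lattice of one-helical-turn sites, each either a specific operator (S) or
non-specific DNA (N).  A state assigns each site bound/unbound and optionally
places RNA polymerase at pR and/or pL.  Weights multiply independent factors:
`c·(B+U)` per occupied S site, `c·U` per occupied N site, `F` per adjacent
occupied pair, and `R`/`L` for RNAP at pR/pL.  Assumptions baked in:

- **Equilibrium, single protein species.** No kinetics; free Apl concentration
  `c` is an externally set scale (in vivo "expression units", in vitro nM).
- **Specific-site weight `c(B+U)`.** A specific site can be engaged either
  specifically or non-specifically, so its association weight is the sum.
  The alternative convention, weight `c·B`, is available as
  `specific_weight_mode="B_only"`; derived single-site constants (1/B) are
  reported independently of the mode, so both conventions are serviced.
- **Uniform nearest-neighbour cooperativity.** One `F` for every adjacent
  bound pair, regardless of the site classes involved.  Longer-range (i+2)
  terms and per-operator affinity differences are deliberately out of scope:
  such extensions are known not to converge to a unique optimum on this kind
  of reporter data.
- **RNAP competition by footprint exclusion.** RNAP at pR requires sites 1–4
  (N₋₁, N₀, O₁, O₂) empty; at pL sites 9–11 (O₇, N₈, N₉).  Both promoters may
  be occupied at once (the wild-type state space is 2048 Apl states + 128 +
  256 + 16 RNAP sectors = 2448).  Footprints are configurable for other
  lattices.  Promoter activity ∝ probability of the RNAP-bound sectors,
  normalised to 1 at `c = 0`; effects of Apl on initiation or elongation are
  ignored.
- **In vitro mode** removes all RNAP species; the unshifted gel band is the
  probability `1/Z` of the empty lattice, and footprint titrations are the
  per-site marginals.

## Parameters

| name | meaning | default | units |
|------|---------|---------|-------|
| B | specific association parameter | 4.55e-5 | per expression unit |
| U | non-specific association parameter | 0.99e-5 | per expression unit |
| F | nearest-neighbour cooperativity | 50.7 | dimensionless |
| R | RNAP·pR composite weight | 6.88 | dimensionless |
| L | RNAP·pL composite weight | 0.29 | dimensionless |
| d | expression units per nM | 1.75 | EU/nM |
| T | temperature for ΔG = −RT ln(·) | 310 | K |

The defaults are the mean of the 20 best global-fit runs on the in vivo
reporter data; `d` comes from a one-dimensional fit of the seven-operator
gel-shift free-DNA curve with B/U and F held fixed.  Free energies use
R = 1.987e-3 kcal/(mol·K).  At 310 K, F = 50.7 gives ΔG_coop = −2.42
kcal/mol and U (17 325 M⁻¹ after calibration) gives −6.01 kcal/mol; note
−RT ln(79 625) = −6.95 kcal/mol for the specific constant, which is reported
as computed (temperature is an explicit argument, and no single temperature
reproduces a rounded −6.9 exactly).

## Numerical choices

- **Enumeration vs transfer matrix.** All observables run on a vectorised
  exhaustive enumeration (cached per lattice); an independent 2×2
  transfer-matrix route computes Z in O(n) and serves as a cross-check (they
  agree to 1e-10 relative in the test suite).  Enumeration refuses lattices
  beyond 20 sites; the transfer matrix rescales its partial sums to avoid
  overflow on long chains.
- **Log-space weights.** State weights are accumulated as logarithms
  (`xlogy` handles empty sites at `c = 0` exactly), so probabilities remain
  finite for any parameter magnitudes; the partition function signals if it
  is still non-finite.
- **Apparent K_D.** Root of `fraction_free(c) = 0.5` by bracketed Brent
  iteration (relative tolerance 1e-8) with geometric bracket widening; the
  root is unique because `fraction_free` is strictly decreasing for
  B, U > 0.  A second criterion (`half_occupancy`: mean specific-site
  occupancy = 50%) is provided because "apparent K_D" is definition-sensitive
  for multi-site fragments; the two differ by ~20–40% on these lattices.
- **Objective.** Per-dataset mean squared residual (the "error divided by the
  number of points" reading), summed over constructs; a mean-absolute variant
  is available behind a flag.
- **Multistart fit.** Start points are drawn log-uniformly inside the bounds
  B, U ∈ [1e-8, 1e-2], F ∈ [1, 1e4], R, L ∈ [1e-3, 1e2] (parameters span
  orders of magnitude).  Local refinement is bounded trust-region
  least-squares in log10-parameter space; a refined run is discarded in
  favour of its start if it ever worsens the objective, so refinement is
  monotone.  The two-round protocol (1000 starts / 100 refinements, then
  bounds shrunk and 200 more refinements) is automated by shrinking bounds to
  the 2×-padded hull of the best decile of round-1 runs — an automated stand-in
  for by-eye inspection of error-vs-parameter profiles, which remain
  exportable via `FitResult.runs_table()`.  The summary averages the 20
  lowest-error runs.  Everything is deterministic for a fixed seed.
- **Gel normalisation.** Raw free-DNA fractions are affinely mapped so the
  zero-Apl lane is 1 and the high-concentration plateau (mean of the top
  `n_plateau` concentrations, default 1 — matching a 7-point titration) is 0,
  then clipped to [0, 1]; a plateau at or above the zero-Apl value is a
  degenerate titration and raises.
- **Bend angles** assume a planar bend: α = 2·arccos(μ_M/μ_E), reported in
  degrees; replicate summaries give mean, SD and a t-interval at a
  configurable confidence level (the field reports "confidence limits"
  without fixing the convention).

## Synthetic data

`aplbind.synth` emulates the measurement structure, not the instruments:

- **Reporter assays.** Model relative-expression curves for the four
  constructs (WT-pR `00111111100`, `00110101100`-pR, `00110001100`-pR, and
  WT-pL with pR inactivated) at 12 concentrations spanning 0–1500 expression
  units (zero plus roughly log-spaced levels; the inducer→expression-unit
  calibration of the underlying assay is not modelled, data are generated
  directly on the expression-unit axis).  10 biological replicates by default
  (the assays used 8–12), multiplicative log-normal noise with σ = 0.05 —
  chosen once as a realistic relative error for replicated LacZ assays —
  then per-replicate renormalisation to 1 at `c = 0`, which reproduces the
  anchor-point correlation of the real normalisation.
- **Gel shifts.** `raw = plateau + (1 − plateau)·fraction_free(c)·noise` on
  the 0–1600 nM titration grid, with a 5% mis-annealed (unbindable) DNA
  plateau; the zero-Apl lane is left noise-free since it is the within-gel
  reference.  Note the affine renormalisation maps the *top-concentration*
  model value to 0, so noise-free round trips recover the model curve only
  up to that value (~2e-5 for the seven-operator fragment), not to machine
  precision.
- **Footprints.** Noise-free per-site occupancy matrices on the published
  3000–10 nM grid, for operators embedded between two non-specific flanks per
  side.

Not emulated: inducer dose-response shape, gel-lane crosstalk or
densitometry artefacts, DNase cutting chemistry, day/batch effects.  Passing
recovery tests therefore demonstrate statistical identifiability of
(B, U, F, R, L) under the stated noise — not robustness to systematic
assay errors.

## Problem sizes

The test suite and the acceptance script run the fit at 100 random starts
with 20 refinements in a single round (the full protocol is 1000/100 + a
second round of 200), and the acceptance script takes the median best-fit F
over 10 independent synthetic experiments of 480 points each.  These sizes
give a stable median (recovered F within one or two units across base seeds)
while keeping a complete run in the minutes range on one CPU.

## Known limitations

- At the mean fitted parameter set the model represses wild-type pR to ~0.18
  of its unrepressed level at 1500 expression units, deeper than the ~0.4
  seen in reporter measurements (the global fit's total error, 0.37, is
  dominated by such high-concentration discrepancies, and the fit is known
  to overstate the difference between the two scrambled-operator
  constructs).  The B-only weight convention moves this to ~0.26; the one-SD
  weak-binding corner of the fit ensemble reaches ~0.37.
- `R` and `L` are composites of RNAP concentration and promoter affinity and
  are only interpretable relatively (R > L ↔ pR is the stronger promoter).
- Apparent K_D values for multi-operator fragments depend on the criterion
  used; both implemented criteria are reported rather than adjudicated.
- The model ignores dissociation during electrophoresis, which plausibly
  explains why predicted weak binding of two-operator fragments is not seen
  in gels.
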