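# Methods

## Model and assumptions

The package models a hepatocellular-carcinoma (HCC) transplantation waiting
list as a static cohort observed "at presentation": `N` patients enter over a
short window, each with a single tumor of size `s` (cm), and `F < N` donor
livers are available.  Four assumptions define the model:

1. **Size-dependent hazards.**  Mortality is an instantaneous rate, constant
   in time at fixed size: `α_nt(s) = α₀(α₁ − e^{−δ₁ s})` for non-transplanted
   patients (concave increasing, saturating at `α₀α₁`) and
   `α_t(s) = α₀ + δ₂ s` after transplantation (linear), with `δ₁ > δ₂`.
   Survival over a horizon `T` is `e^{−α(s)T}`.  Tumor growth over time is
   *not* modelled; its effect is folded into the size-at-presentation
   hazards.
2. **Size as gravity.**  Both hazards increase monotonically in `s`.
3. **Scarcity.**  `F < N`, enforced at the type level.
4. **Exponential sizes.**  `p(s) = λ e^{−λs}`, mean `1/λ`.

`α₁ = 2` is the standing choice: it is the unique multiplier for which the
two hazards coincide at `s = 0` (a vanishing tumor gains nothing from a
graft), for any `α₀`.  Because `α_nt` is concave and saturates while `α_t`
grows linearly, the curves cross at a single positive size `s×`
(`crossing_size`); transplantation helps below `s×` and harms above it.
`calibrate_delta1` inverts the crossing condition,
`δ₁ = −ln(1 − δ₂ s×/(α₀(α₁−1)))/s×`, so a desired crossing can be imposed.

## Default parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `alpha0` | 0.048 | 1/year | baseline hazard (both groups at `s=0`, given `α₁=2`) |
| `alpha1` | 2 | — | saturation multiplier; 2 enforces coincidence at zero |
| `delta1` | 0.3 | 1/cm | shape rate of the non-transplanted hazard |
| `delta2` | 0.006 | 1/(year·cm) | slope of the transplanted hazard |
| `lam` | 0.3 | 1/cm | exponential size rate → mean tumor 3.33 cm |
| `T` | 5 | years | survival horizon |
| `N` | 1500 | patients | waiting-list size |
| `F` | 500 | grafts | donor-liver supply |
| `S_M` | 5 | cm | Milan single-nodule size limit |

The default `δ₁ = 0.3` places the hazard crossing at 7.03 cm
(`≈ calibrate_delta1(7) = ln 8/7 = 0.2971`), which is what makes the
mortality curve non-monotone with an interior optimum near 7 cm and an
equivalent threshold near 10 cm.  A much shallower `δ₁` (e.g. 0.02, below
`δ₂/α₀ = 0.125`) makes the initial slope of `α_nt` smaller than that of
`α_t`, the curves never cross for `s > 0`, transplantation is harmful at
every size, and the optimal cutoff collapses to the boundary `s* = 0`; the
package accepts such configurations and reports the boundary minimum
explicitly.  `T = 0` is allowed as a degenerate horizon (everyone survives),
which also yields the graft-utilization identity `TS(T=0) = F(1 − e^{−λs₀})`.

## Allocation policies

A policy is a cutoff `s₀` plus a size-bias `g(s) ∈ [0,1]` (constant, step,
or piecewise-linear table in the config).  Below the cutoff the transplanted
density is `x(s) = g(s)(F/N)λe^{−λs}`; the remainder `y(s) = p(s) − x(s)` is
not transplanted; above the cutoff `x = 0`.  Derived quantities:

- **Full-utilization threshold** `s_F = −ln(1 − F/N)/λ`: the cutoff at which
  transplanting *everyone* below it consumes exactly `F` grafts (1.35 cm in
  the baseline).
- **Graft utilization** of the proportional policy:
  `F(1 − e^{−λs₀}) < F` at any finite cutoff — expanding eligibility beyond
  `s_F` under proportional sharing always leaves some livers unused.  Counts
  are reported as real numbers; the continuum model does not round, the
  Monte-Carlo module handles integer grafts.
- **Milan split** (`milan_summary`): proportions of (non-)transplanted
  patients below/above `S_M`, with two regimes.  *Scarce*
  (`F < N(1−e^{−λS_M})`): all grafts go below `S_M`
  (`p_t_below = F/N`, `p_t_above = 0`).  *Rich*: the formulas switch to
  proportional sharing over all sizes (`p_t_below = (F/N)(1−e^{−λS_M})`,
  `p_t_above = Fe^{−λS_M}/N`).  The non-transplanted components and the
  aggregate identities (`p_nt` sums to `1−F/N`, `p_t` to `F/N`) are
  continuous at the regime boundary; the transplanted *split* is not,
  because the two regimes encode different policies.  This is a property of
  the model, not a defect of the implementation.

## Outcome integrals and optimization

Expected survivors are size-resolved integrals of `density × survival`:
transplanted `TS = F∫₀^{s₀} λe^{−λs}e^{−α_t(s)T}ds` and non-transplanted
`NTS = N(1−F/N)∫₀^{s₀} … + N∫_{s₀}^∞ λe^{−λs}e^{−α_nt(s)T}ds`;
`M(s₀) = N − TS − NTS`.  Numerical choices:

- Adaptive quadrature (`scipy.integrate.quad`) with absolute tolerance
  1e−12 on proportions before scaling by `N` or `F`.
- The infinite tail is integrated exactly on the transformed variable
  `u = e^{−λs}` (finite interval `[0, e^{−λs₀}]`, with
  `e^{−δ₁s} = u^{δ₁/λ}`), not by truncation.
- `TS` has the closed form `F e^{−α₀T} λ/(λ+δ₂T)(1 − e^{−(λ+δ₂T)s₀})`, kept
  as an independent cross-check of the quadrature (tests assert agreement to
  1e−8 relative), as are the `s₀ = 0` and `s₀ → ∞` closed forms of `NTS`
  when `λ = δ₁`.

The derivative `dM/ds₀ = −Fλe^{−λs₀}[π_t(s₀) − π_nt(s₀)]` vanishes exactly
where the hazards cross, so `argmin M = s×` whenever a positive crossing
exists — a structural identity the tests assert on randomized parameter
draws.  `optimal_threshold` does a coarse grid search (default 0.05 cm over
[0, 15]) followed by a Brent root solve of the derivative when the minimum
is interior; ties break to the smallest cutoff; boundary minima are reported
rather than raised.  `equivalent_threshold` brackets `M(s) = M(S_M)` on
`[s*, s_hi]` with `s_hi` grown geometrically up to the `1 − 1e−10` size
quantile and solves to 1e−8 cm (reported rounded to 0.1 cm in human-readable
output); it returns `None` with a logged diagnostic when no root exists
(boundary minimum, or `M` never recrosses the Milan level).

## Monte-Carlo simulator

`sample_cohort` draws `N` i.i.d. exponential sizes, transplants each patient
with `s ≤ s₀` independently with probability `g(s)F/N` (Bernoulli thinning
that mirrors the continuum density `x(s)`), revokes uniformly-random excess
transplants if the realized count exceeds the integer supply `F` (logged),
and assigns each patient an exponential death clock at the appropriate
hazard — the constant-in-time reading of the survival model.  One master
`SeedSequence` spawns per-replicate child seeds, so every run is
reproducible bit-for-bit.  `mc_mortality` averages death counts over
replicate cohorts and reports a standard error; it serves as the
independent oracle for the deterministic integrals (agreement within 3 SE in
the tests at 300 replicates).

What the generator emulates: the theoretical population itself — sampling
noise around the deterministic integrals, integer grafts, seed-stable
reproduction.  What it does not: real waiting-list dynamics (continuous
arrivals and departures, competition with non-HCC candidates, MELD-based
prioritization), tumor growth or treatment between listing and transplant,
multi-nodule presentations, or measurement error in imaging-based size.
Passing tests therefore validate internal consistency of the model and its
implementation, not the clinical accuracy of the hazard forms or of `λ`.

## Size-distribution fitter

`fit_size_distribution` uses the exponential MLE `λ̂ = 1/mean`, a Wald 95%
interval on the mean with `σ̂ = mean` (exponential property),
`mean·(1 ± 1.96/√n)`, and an R² between binned relative frequencies
(default 1 cm bins on [0, 12]) and the fitted density at bin midpoints.  At
`n = 327` and mean exactly 10/3 the interval is [2.97, 3.69]; quoted
two-decimal→one-decimal roundings of such intervals are sensitive to whether
the mean is rounded before the interval is formed (a mean pre-rounded to 3.3
gives [2.94, 3.66] → [2.9, 3.7]).  The fitter always reports the unrounded
interval.

## Problem sizes and runtimes

The shipped configuration evaluates the mortality curve on a 0.01 cm grid
over [0, 15] (1,501 quadrature points, ~1 s), uses 300 Monte-Carlo
replicates of 1,500 patients for oracle comparisons, and 200 synthetic
cohorts of 327 patients for fitter calibration; the full test suite runs in
a few seconds on one core.

## Known limitations

- Single-compartment HCC list: no interaction with non-HCC candidates for
  the same grafts; `F` is taken as the supply already earmarked for HCC.
- The hazard forms are ad hoc (chosen for qualitative shape: concave
  saturating vs linear); conclusions are robust to other concave/convex
  pairs but parameter values are not transferable.
- Size is a scalar; the multi-nodule clauses of the Milan criteria are out
  of scope.
- The equivalent threshold compares expected deaths only; it ignores
  variance, equity between size classes, and graft wastage (which the
  utilization output quantifies separately).
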