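# Methods

This note records the statistical model the package implements, the
numerical choices behind it, and what the synthetic-data generator does and
does not emulate.

## Model and estimators

Right-censored data are pairs t_i = min(T_i, U_i), δ_i = 1{T_i ≤ U_i}. The
joint law of survival time T and censoring time U is modelled with an
Archimedean copula on the survivor scale,
P(T > t, U > u) = φ_α⁻¹[φ_α{S_T(t)} + φ_α{S_U(u)}], where the generator
φ_α is continuous and strictly decreasing on (0, 1] with φ_α(1) = 0 and
φ_α(0⁺) = ∞. The copula-graphic estimator inverts this relation
nonparametrically: processing subjects in time order, each event
contributes φ_α((Y−1)/n) − φ_α(Y/n) to a running sum in generator space
(Y the at-risk count, n the group size), and the curve value after each
event time is φ_α⁻¹ of the sum. Two structural identities anchor the
implementation and are enforced by tests:

- **Independence limit.** With φ(t) = −log t the sum telescopes into the
  Kaplan–Meier product-limit estimator, exactly (≤ 1e−12 observed).
- **No-censoring limit.** With all δ = 1 the sum telescopes to
  φ(#survivors/n) for *any* generator, so the curve is the empirical
  survivor function.

**Tie handling.** The estimator's printed single-event form does not define
behaviour at tied times. This package processes tied events sequentially,
decrementing the at-risk count by one per event, with events preceding
censorings at the same time (the product-limit convention). This is the
unique rule under which the independence limit reproduces KM with ties and
the no-censoring limit holds; it is this package's deliberate refinement,
not a convention inherited from elsewhere. Because the at-risk count at
sorted position i is then exactly n − i, the generator increments depend
only on (copula, group size) and are precomputed once and reused across
all permutations.

**Degenerate cases.** An event with at-risk count 1 drives the sum to
φ(0) = ∞ and the curve to exactly 0 from that time on. Generator values
above 1e300 are treated as the infinite sentinel; φ⁻¹ of the sentinel is
exactly 0, and φ⁻¹(0) is exactly 1. Beyond the largest observed time the
curve extends as a constant; no extrapolation is attempted.

## Copula families

Clayton φ_α(t) = (t^−α − 1)/α (α > 0, τ = α/(α+2)), Gumbel
φ_α(t) = (−log t)^{α+1} (α ≥ 0, τ = α/(α+1)), Frank
φ_α(t) = −log[(e^{−αt} − 1)/(e^{−α} − 1)] (α ≠ 0). Clayton and Gumbel
admit only positive dependence; Frank admits τ ∈ (−1, 1) \ {0} and its tau
is odd in α. Frank's tau uses the first Debye function, evaluated by
adaptive quadrature of ∫₀^α t/(e^t − 1) dt at relative tolerance 1e−10
with the integrand defined by its limit 1 at t = 0. `alpha_from_tau`
inverts the closed forms analytically (Clayton 2τ/(1−τ), Gumbel τ/(1−τ))
and solves Frank by Brent root-finding to |τ residual| < 1e−8.

Numerical guards: |α| < 1e−8 for Clayton/Frank is routed to the
independence generator (both converge to −log t, and the exact formulas
cancel catastrophically there); Clayton's φ at tiny v is computed via
expm1/log to avoid overflow in v^−α.

Two grid labels in the published sensitivity table (Clayton α = 4 and
Gumbel α = 2, both labelled τ = 0.75) are inconsistent with the printed
tau relations, which give 2/3 for both; this package follows the formulas
and reports τ = 0.67 for those cells.

## Risk stratification

PI_i = Σ_j β̂_j x_ij with signature weights taken as inputs (the
copula-adjusted weight estimation procedure is out of scope; the two
published 16-gene signatures ship as fixtures). The cutoff defaults to the
training-sample median — the choice with balanced group sizes and the best
power in the motivating study; quartile cutoffs are exposed for
sensitivity to the cutoff itself. Ties at the cutoff go to the good group
(PI ≤ c). The univariate Cox screen delegates each one-gene fit to
lifelines (partial likelihood, Breslow tie handling, two-sided Wald test)
with Newton tolerances tightened to 1e−12 so fitted coefficients are
optimizer-precision; monotone-likelihood genes are flagged, excluded and
logged. Harrell's c-index counts pairs whose smaller observed time is an
event; PI ties count 1/2.

## Separation test

D = (1/τ)∫₀^τ (Ŝ_Good − Ŝ_Poor) dt with τ = min of the two group maxima of
observed time, regardless of status; the integral is the exact
piecewise-constant sum, no quadrature. RMSTD = τ·D by definition (stored
as a derived property, so the identity is exact). The permutation scheme
reassigns the (time, status) pairs to subjects uniformly at random while
PI values — hence group labels and sizes — stay fixed; the horizon is
recomputed per permutation, so each D_r is the full statistic. The default
p-value is the one-sided rule p = #{D_r > D}/N with strict inequality and
no continuity correction. The alternative hypothesis is naturally
two-sided, and a `two_sided` mode (|D_r| > |D|) is provided; the default
follows the one-sided convention because a *negative* D (good group dying
faster) is evidence against the prognostic index, not for it. N defaults
to 10,000; N = 200 is a documented fast setting. All randomness flows
through a seeded numpy Generator and the seed is recorded in every result.

The grid driver derives each cell's seed as CRC32(master_seed | family |
alpha) masked to 31 bits, so results are independent of grid order,
extending the grid never perturbs existing cells, and any cell can be
reproduced by a standalone `permutation_test` call with the derived seed.

## Synthetic data

Copula pairs are drawn by conditional inversion: V uniform, then W solving
∂C(v, w)/∂v = φ'(v)/φ'(C(v, w)) = p by 60 rounds of vectorized bisection
(interval width < 1e−15, well inside the 1e−10 tolerance), using analytic
generator derivatives. One code path serves all families including
negative-dependence Frank; the Clayton closed-form conditional inverse
serves as an independent oracle in tests, not as the implementation.
Margins are exponential(rate) or Weibull(shape, scale), inverted on the
survivor scale (T = S_T⁻¹(V)), so positive copula dependence in (V, W)
transfers to positive Kendall dependence in (T, U).

The cohort generator draws one latent standard-normal level per signature
gene and codes it into within-sample quartiles {1, 2, 3, 4}, matching the
quartile-coded expression data of the motivating lung cohort (n/4 subjects
per level, up to rounding). Survival follows a proportional-hazards law
with hazard multiplier exp(PI − mean PI); the centering fixes the time
scale without changing relative risks. Censoring is tied to survival
through the copula marginally by default; a `censoring_conditional` switch
applies the same hazard multiplier to the censoring margin, emulating
cohorts where drop-out tracks disease severity.

What the generator does **not** emulate: gene–gene correlation, non-PH
effects, covariate-dependent copulas, or the administrative censoring
pattern of a real trial. Passing tests therefore demonstrate correctness
of the estimators and test under the stated model, not robustness to
real-data violations of it.

## Study conditions used in the checks

- Tau conversions and all structural identities are deterministic and run
  at full precision.
- Consistency: n = 2,000 from Clayton τ = 0.5 with unit-exponential
  margins; CG with the generating copula stays within 0.05 of e^{−t} at
  the event-time deciles and strictly beats KM on the same draw.
- Permutation calibration: 500 null datasets (n = 40, PI independent of
  survival, ~30% censoring) at N = 400 give a rejection rate within 3
  binomial standard errors of 0.05; a 6-subject case is checked against
  exhaustive enumeration of all 720 relabelings.
- Dependence-sweep trend: 10 replicate cohorts (n = 120, two-gene
  signature with weights ±0.5, Clayton τ = 0.8 between T and U, censoring
  margin exp(2) and outcome-linked via the conditional switch). Averaged
  over cohorts, grid p-values decrease strictly as assumed positive tau
  rises — the qualitative pattern reported for the real lung cohort,
  whose signature was itself developed under strong positive dependence.
  The direction of this trend is a property of the censoring structure,
  not a universal law: with light or outcome-independent censoring the
  sweep can be flat or reversed, which is precisely why the sensitivity
  analysis is worth running.

## Known limitations

- No variance or confidence bands for the CG estimator.
- The copula-adjusted coefficient estimator and cross-validated-c-index
  selection of α used to *build* signatures are out of scope; weights are
  consumed as inputs.
- The Frank generator at |α| > ~700 overflows to the independence-like
  regime of the sentinel logic; grids in practice use |α| ≤ 30.
- The permutation p-value has granularity 1/N and no continuity
  correction by default (an add-one variant is available in the API).
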