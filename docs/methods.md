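# Methods

## Model and estimation

Each biomarker in each group follows the Gaussian cosinor model
`Y_i = A cos(2π/P (t_i − φ)) + M + ε_i`, `ε_i ~ N(0, σ²)`, with the period
`P` a run-level constant (default 24 h; never estimated).  The linearized
regression on `{sin(ωt), cos(ωt), 1}` (ω = 2π/P) yields `(a, b, M)` by
ordinary least squares; amplitude and acrophase follow from the exact
bijection `A = √(a²+b²)`, `φ = atan2(a, b)/ω mod P` (so `a = A sin(ωφ)`,
`b = A cos(ωφ)`).  The residual variance uses the maximum-likelihood
denominator *n* (not n−3) so that the reported log-likelihood
`−(n/2)(log 2πσ² + 1)` is the exactly maximized Gaussian likelihood entering
every likelihood-ratio statistic; this internal consistency matters more
here than unbiasedness of σ̂².  A fit needs n ≥ 5 per group (4 parameters
plus one residual degree of freedom) and a time design that is not
degenerate mod P.

Flat fits (`A ≈ 0`) report `φ = 0` with a `degenerate` flag; numerically
perfect fits (RSS < 1e−12·TSS) set the same flag and make the rhythmicity
p-value exactly 0 through a dedicated branch, since the likelihood is
unbounded there.  Callers must consult the flag before interpreting phases.

Rhythmicity per group is tested against the intercept-only null.  The
default is the exact F test `((RSS₀−RSS₁)/2)/(RSS₁/(n−3)) ~ F(2, n−3)` —
exactly calibrated at any n under the model — with the asymptotic LRT
`n log(RSS₀/RSS₁) ~ χ²₂` available because the downstream joint tests are
likelihood-ratio based.

## Types of rhythmicity

The categorizer is a sequential two-stage selection on the per-group
rhythmicity p-values.  Stage 1 tests "rhythmic in at least one group" with
`p₁ = 1 − (1 − min(p_I, p_II))²`, the Šidák combination of the minimum of
two independent p-values — exactly uniform when both groups are arrhythmic.
Stage 2, evaluated only among stage-1 discoveries, tests "rhythmic in the
second group too" with `p₂ = max(p_I, p_II)`; under the stage-2 null
(exactly one group rhythmic) this behaves like the arrhythmic group's
uniform p-value, and the selection event is driven by the rhythmic group's
small p-value, so the two stages are effectively independent.  The scheme
therefore bounds both error events of interest — arrhythmic → any rhythmic
category, and one-group-rhythmic → RhyBoth — at the stage level; the
simulation harness verifies both bounds empirically.  The construction sits
behind a small interface so a different staged scheme can replace it
without touching callers.  Stage-2 ties `p_I = p_II` (probability zero for
continuous p-values) resolve to RhyI, logged.

Multiplicity across genes defaults to Benjamini–Hochberg at level 0.05 per
stage (stage 2 within the stage-1 discovery set); raw-α thresholds are kept
for the simulation experiments where per-gene rates are the quantity of
interest.  Venn thresholding and AIC/BIC model selection over the four
joint two-group models (k counting all mean and variance parameters, 4/6/6/8)
are implemented as comparators only.  An adaptively weighted Fisher
comparator is a possible extension, not implemented.

## Differential rhythmicity tests

All two-group tests are Gaussian LRTs against the free model (separate
`(a, b, M, σ)` per group — the groups are different tissues or cohorts, so
per-group variances are kept throughout; a pooled-variance variant is not
the default).

**DR fitness.**  Equal rhythm fitness is formalized as equal
signal-to-noise ratio `A_I/σ_I = A_II/σ_II = η`; under full-cycle sampling
the population R² is `snr²/(snr²+2)`, so this is equality of R² without
being tied to the noise level alone (a Δσ² test is deliberately not
provided: a gene can double its noise and amplitude together without any
change in how rhythmic it looks).  The constrained likelihood is maximized
over `(η, φ_I, φ_II)` by Nelder–Mead with closed-form inner updates: given
`(η, φ)` for one group, profiling M and maximizing over σ reduces to the
quadratic `nσ² + η S_xy σ − S_yy = 0`, whose positive root is the inner
MLE.  The optimizer starts at the unconstrained estimates with η at the
sample-size-weighted pooled SNR; up to three perturbed restarts trigger
only on failure (non-convergence, or a negative LRT beyond 1e−6) — the
profiles are smooth and low-dimensional, and unconditional restarts would
triple the cost of the Monte-Carlo experiments without changing optima.
Statistic `2Δloglik`, df 1.

**Global DR parameter test.**  Equality of (φ, A) across groups is exactly
equality of the linearized `(a, b)`, so the constrained model shares
`(a, b)` (plus M when the declared set includes the MESOR) with per-group
variances.  It is fitted by alternating weighted least squares and
closed-form variance updates — monotone coordinate ascent to the joint MLE
(verified against direct optimization and against brute-force grid
enumeration in the tests).  Df 2, or 3 with MESOR.

**Post-hoc tests.**  Single-parameter equality against the free model:
shared-φ by a 1-D profile over φ ∈ [0, P) (480-point grid plus bounded
refinement; per-group amplitude clipped at 0, M and σ closed-form),
shared-A by Nelder–Mead over `(A, φ_I, φ_II)`, shared-M by 1-D bounded
search with closed-form per-group `(a, b, σ)`.  Post-hoc p-values are
computed only for genes whose global test rejected, and only for the
parameters declared before testing; this gating is what controls the
per-gene family error across the parameter set — the full-null simulation
confirms the family rate stays at the nominal level.  Across genes, BH is
applied to the global p-values; post-hoc p-values are reported raw within
the gated set.

**Finite-sample reference.**  For a Gaussian linear model with profiled
variance, the LRT for q mean-parameter restrictions has the exact null
expectation `E[W] = n(ψ((n−p+q)/2) − ψ((n−p)/2))` (ψ the digamma function;
p free mean parameters), because `W = n log(RSS₀/RSS₁)` and log-χ² moments
are digamma values.  At n = 48 total and p = 6 this is ≈ 1.14·q — the raw
χ² reference is visibly anticonservative at circadian sample sizes (≈ 0.07
at nominal 0.05).  All global and post-hoc p-values therefore rescale W by
this analytic Bartlett factor before the χ² lookup.  The same factor is
applied to the fitness LRT: its constraint is not a pure mean-parameter
restriction, but the factor's leading term is the RSS/n variance-MLE bias
common to all these profile LRTs, and the statistic's simulated null mean
matches the derived factor to three decimals.  `reference="chisq"` restores
the raw asymptotic reference on every test.  The Bartlett-corrected LRT is
still asymptotically χ²; the correction vanishes as n grows.

**Conventions.**  All deltas are comparison minus reference (II − I).
Phase differences are wrapped to (−P/2, P/2], the antipodal difference
mapping to +P/2; positive Δφ means the comparison group peaks later.

## Eligibility and orchestration

The fitness test runs on every gene rhythmic in at least one group
(RhyI ∪ RhyII ∪ RhyBoth): a fitness change is interpretable whenever one
group has a rhythm to lose or gain.  The parameter tests run on RhyBoth
genes only: Δφ, ΔA are defined only when both groups actually oscillate.
BH is applied within each test family.  Genes where an optimizer fails
after restarts carry a NaN p-value and a flag — never a silent 1.0.

## Synthetic data

The generator draws data exactly from the Gaussian cosinor model, per gene
and group, with explicit seeds everywhere and no global random state.  The
default design is 24 samples per group evenly spaced over one period — the
common around-the-clock collection design — with a uniform-random
alternative for jittered collection times.  Default simulation conditions
follow the regimes the tests are specified for: noise SD 1, amplitudes
expressed as SNR (3 for clearly rhythmic genes in the classification
experiments, 2 for the power scenarios), MESOR 10, phases uniform on
[0, P) in the mixed fixture; null scenarios set the constrained quantity
exactly equal across groups (e.g. SNR 2 via A = 2, σ = 1 against A = 1,
σ = 0.5).  The 100-gene mixed-truth fixture (30 RhyBoth / 20 RhyI /
20 RhyII / 30 Arrhy) is the end-to-end check.

What the generator does *not* emulate: count noise (data are Gaussian on
the log scale by construction), non-sinusoidal waveforms, correlated genes,
batch effects, or subject-level repeated measures.  Passing tests therefore
certify the statistical machinery under its own model — calibration, error
control, power, and estimator consistency — not robustness to real-data
violations of the cosinor assumptions.

## Numerical choices

* Optimizers: Nelder–Mead, `xatol 1e−8` / `fatol 1e−10`; 1-D profiles use
  bounded Brent refinement of a coarse grid (`xatol 1e−10`).
* LRT statistics are clipped at 0; values below −1e−6 before clipping
  trigger restarts, then a flag.
* Degeneracy thresholds: RSS < 1e−12·TSS, A < 1e−12.
* A perfectly rhythmic zero-noise group has unbounded SNR, so the fitness
  test against any finite-noise group rejects with p = 0 (flagged);
  a zero-noise *constant* group leaves the SNR undefined and yields a
  flagged NaN.
* BH adjustment delegates to statsmodels' step-up implementation.
* Heatmap ranking: rhythmicity p ascending, ties by R² descending (the
  ordering is exposed as a table so it is testable without rendering).
* Circos radial encoding: linear in Δφ over (−P/2, P/2] around a unit
  reference circle, Δφ = 0 on the circle, +P/2 at the outer band edge.

## Limitations

Only sinusoidal rhythms (no periodogram or nonparametric detection), only
two groups, no period estimation, Gaussian noise only, and no batch or
covariate adjustment.  The post-hoc p-values carry no selective adjustment
beyond the global gate; the gated family-error simulation is the
operational guarantee.  Problem sizes in the simulation experiments
(2000/1000 replicates, n = 24 or 40 per group, 2000 genes for the
classification rates) were chosen to give Monte-Carlo envelopes of about
±0.01–0.02 around the nominal 0.05 level.
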