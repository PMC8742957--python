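# Methods

This note documents the models behind `celsignal`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Signaling score

The score of a treated well against its control is the per-minute summed
Cell Index difference over the window after agonist addition,
`S = Σ_{i=0}^{240} (T_i − C_i)`. The bounds are **inclusive** — 241
terms — so a constant +1.0 offset scores exactly 241, not 240. We follow
the summation limits of the defining equation rather than the looser
"240-minute period" phrasing; tests encode the 241 constant explicitly.

Traces recorded on any grid are linearly interpolated onto the 1-minute
grid before summation; the instrument sampling interval is therefore
unconstrained as long as the trace covers `[0, window]`. Samples at
negative times (pre-addition baseline) are accepted and ignored by the
scorer. No baseline normalization is applied beyond the control-well
subtraction — that subtraction *is* the normalization in this score
definition.

**HER decomposition.** From the five-well scheme, the HER2 score is the
dimer contribution lost under the blocking antibody summed over both
ligand arms, `Σ(CF1−CDF1) + Σ(CF2−CDF2)`; the blocked-well residuals
give HER3/4 = `Σ(CDF1−C)` and HER1 = `Σ(CDF2−C)`. This is the minimal
decomposition consistent with the CF/CDF well design; whether the
original assay weights or thresholds the CF−CDF difference is not
public, so the plain sum is the default policy. Replicates are averaged
(mean, not median — wells are typically run in duplicate, where robust
estimators add nothing).

**Calls.** A pathway is positive iff its score is at or above its
cutoff. The combined call requires c-Met positivity plus at least one
positive HER-family pathway. The c-Met cutoff defaults to 250 signaling
units; HER cutoffs default to the same value but are pure configuration —
no published HER cutoffs exist for this decomposition.

## Cohort mixture model and model-based ROC

Scores are fitted with a univariate K-component normal mixture by EM.

* Initialisation: one quantile-partition start (K equal-count slices,
  pooled SD) plus 9 random restarts (means drawn from the data); best
  log-likelihood kept. This avoids label-switching flakiness at cohort
  sizes near n = 79.
* SD floor: `1e-3 ×` sample SD, the standard guard against the unbounded
  likelihood of a component collapsing onto one point. A fit is
  degenerate only if no restart achieves a finite likelihood.
* Convergence: relative log-likelihood change `< 1e-8` (max 500
  iterations). For K = 1 the EM fixed point is the closed-form MLE and
  is returned directly.
* Components are reported in ascending mean order; "positive" defaults
  to the right-most (highest-mean) component.

The number of components is tested by a **parametric bootstrap** LRT
(default 199 replicates): mixture LRTs violate the regularity conditions
of the chi-square reference, so the null distribution of `2Δℓ` is
simulated from the fitted smaller model. p-values use the add-one
convention `(1 + #{2Δℓ* ≥ 2Δℓ})/(B + 1)`.

The ROC is computed from the fitted model, not from empirical labels:
`sens(c) = Φ((μ_pos − c)/σ_pos)` and FP is the renormalized-weight
mixture tail of the remaining components. Renormalizing the non-positive
weights (rather than mixing over all components) makes FP the
false-positive probability *conditional on belonging to the non-positive
sub-population* — the convention used in the original derivation this
package mirrors, kept deliberately. `select_cutoff` returns the smallest
grid cutoff whose FP meets the bound; since both curves are
non-increasing in the cutoff this maximizes sensitivity subject to the
constraint.

**Prevalence** uses a Wilson score interval by default (Wald available);
the CI method is always recorded in the output because normal-theory
intervals at other confidence levels can differ materially at n = 79.
The **KS comparison** offers an asymptotic p (Kolmogorov limit) and a
permutation p computed by exhaustive enumeration of group reassignments
when there are ≤ 100 000 splits (exact; the observed split is included
in the count) and random splits with the add-one convention otherwise.
Ties are handled by the pooled right-continuous step-function
convention.

## Dose-response and combination index

Titration scores are normalized to a fraction affected against an
explicit reference maximum and baseline; the inhibitor/agonist
orientation is always a declared flag, never inferred from the data.
Values are clipped to `[ε, 1−ε]`, ε = 0.01 by default, because the
median-effect transform diverges at 0 and 1; every clip is logged, and a
titration whose points are all clipped to one bound is rejected as
uninformative. Baseline subtraction before scaling is the default and is
configurable.

The median-effect fit is ordinary least squares on
`log10(fa/fu)` vs `log10 d`; the 4PL fit is bounded nonlinear least
squares (floor/ceiling/inflection/slope) initialized from that line,
with confidence intervals on `log10 Dm` using t-quantiles — residual
degrees of freedom in a five-point design are tiny, and z-quantiles
visibly under-cover there. The reported IC50 is the 4PL inflection
(relative IC50), with the median-effect `Dm` alongside. The five-point
1000-fold design is implemented as geometric spacing (factor
`1000^(1/4) ≈ 5.62`); only the span, not the spacing, of the original
design is documented, so even spacing on the log scale is the natural
reading.

The combination index at a shared effect level uses each agent's own
median-effect inversion `Dx(fa) = Dm (fa/(1−fa))^{1/m}`. The mutually
exclusive two-term form is the default (matching the reported behavior
of these drug combinations); the non-exclusive cross-term form is
available behind a flag. Interaction classification uses a dead band
(synergy < 0.9, antagonism > 1.1 by default) to avoid noise-driven flips
around 1; set both thresholds to 1 for the bare reading.

## Efficacy statistics

Percent inhibition is `100·(1 − (S_drug − S_base)/(S_agonist −
S_base))`; negative values mean the drug *enhanced* the agonist response
(feedback release), values above 100 mean suppression below baseline.
Cross-talk matrices evaluate this for every agonist × antagonist pair,
averaging replicates, and fail loudly (listing the absent wells) if any
cell, reference or baseline is missing.

Xenograft efficacy is percent tumor reduction from endpoint mean
volumes, `100·(1 − V̄_t/V̄_c)` — not a growth-rate or AUC measure, which
is a documented, switch-worthy choice since the original tabulation does
not state its definition — with a Welch (unequal-variance) t-test by
default. Excluded animals are taken from an explicit list, never
inferred.

## Synthetic-data generator

The generator produces inputs with the statistical structure the
analysis assumes; its defaults are the study conditions used throughout
the tests.

* **Cohort scores** come from a three-component normal mixture. The
  right-most component is the published (weight 0.48, mean 446, SD 195).
  The two lower components, (0.33, 40, 35) and (0.19, 130, 55), are
  *synthetic defaults*, not published values: they were chosen so that
  the model FP at the 250-unit cutoff stays below 1% (it is 0.53%) and
  the top two component means are more than four SDs of the middle
  component apart (316 > 220), the two qualitative constraints reported
  for the fitted population.
* **Traces** follow `baseline + A_eff · k(t)/Z + N(0, σ)` with the
  rise-then-decay kernel `k(t) = (1−e^{−t/τ_r})e^{−t/τ_d}`, defaults
  τ_r = 15 min, τ_d = 600 min (synthetic; chosen to match the
  characteristic shape of agonist-evoked impedance responses). `Z`
  normalizes the kernel's per-minute sum over the 240-min window, so the
  noiseless score of a well equals its amplitude `A_eff` exactly — the
  discrete-sum analogue of normalizing by the kernel integral, chosen so
  score-recovery tests are exact rather than quadrature-limited.
* **Amplitudes.** `A_eff` is the patient's pathway capacity times the
  driving ligand's receptor occupancy `fa(d) = d^m/(d^m + Dm^m)` times a
  per-drug modulation `1 − fa_d · X[d][p]` (clamped at 0 from below).
  `X = 1` is a full on-target block at saturation, `0 < X < 1` partial
  cross-talk, `X < 0` enhancement — this signed coupling reproduces
  negative percent inhibition by construction. Agonist potencies default
  to `Dm = dose/9` with slope 1, making the standard assay doses (3 nM
  NRG1b, 0.3 nM EGF, 0.08 nM HGF) the EC90, as the assay design intends.
  HER2 heterodimer signal is split between the NRG1b and EGF arms
  (default 50/50) and removed in antibody-blocked (CDF) wells.
* **Combination surfaces** solve
  `d₁/Dx₁(fa) + d₂/Dx₂(fa) + α (d₁/Dm₁)(d₂/Dm₂) = 1` for `fa`. At
  α = 0 this is exactly Loewe additivity, so the downstream CI analysis
  must return 1 there — the single-parameter deviation is the smallest
  model with that testable property. If the interaction term alone
  exceeds 1 the effect saturates and fa is clamped just below 1.
* **Xenografts** grow exponentially, `V₀ e^{g(1−e)t}`, with
  mean-preserving lognormal noise; the closed-form expected reduction at
  day T is `100·(1 − e^{−geT})`, which the Monte-Carlo tests recover.
  Defaults g = 0.08/day, V₀ = 150 mm³, 21 days, CV 0.25, 10 mice/arm,
  measurements every 3 days, mirroring the reported study design.

What the generator does **not** emulate: receptor-level mechanism (no
dimerization or trafficking ODEs), drug pharmacokinetics, plate-edge or
drift artifacts, heteroscedastic or autocorrelated instrument noise, and
inter-plate batch effects. Passing tests therefore demonstrate that the
*analysis chain* is correct under its stated assumptions, not that those
assumptions hold for any particular instrument or tumor model.

## Problem sizes and determinism

Simulation-based tests use sizes chosen to keep the full suite fast
while leaving Monte-Carlo error well inside the asserted bounds: 50
seeds × n = 5000 for mixture recovery, 10⁶ draws for the ROC oracle, 500
seeds for dose-response recovery, 200 replicates for xenograft
simulations, ≤ 13 pooled observations for exhaustive KS enumeration.
Every generator takes an explicit seed; `scripts/acceptance.py` derives
all randomness from its `--seed` argument, and the pipeline writes no
timestamps, so identical configurations produce byte-identical outputs.

## Known limitations

* EM parameter recovery near the tolerance bounds reflects the sampling
  spread of the MLE itself; with strongly overlapping components the
  per-seed estimates of the top component can miss ±15 units even at the
  global optimum (verified against an independent mixture
  implementation). Seed-averaged estimates remain unbiased.
* The HER decomposition is a policy, not the original proprietary HER2
  formula; scores are comparable within this package, not across
  implementations.
* The printed 95% CI convention of the original prevalence figure is not
  reproducible with standard 95% constructions; the Wilson interval is
  reported with its method label instead.
* The permutation KS p is exact only for small samples; larger inputs
  fall back to Monte-Carlo with the add-one convention.
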