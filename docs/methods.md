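# Methods

This note records the models implemented in `scnclone`, the parameter
conventions they use, the numerical choices behind the simulators, and the
limits of what the synthetic-data tests can show.

## 1. Proof-of-principle Moran model (`scnclone.moran`)

A population of N granulocyte-precursor cells contains i carriers of the
*CSF3R* truncation; at each step a uniformly chosen cell dies and is
replaced by the offspring of a cell drawn with odds r = 1 + s in favour of
the mutant.

* **Fixation probability.** P[fix] = (1 − (1−s)ⁱ)/(1 − (1−s)ᴺ).  This is
  the classical closed form with (1−s) approximating the exact per-copy
  factor (1+s)⁻¹; the relative deviation from the exact absorbing-chain
  solution is ≈ s at i = 1 (measured: 0.5%…10% for s = 0.005…0.1) and
  decays as i grows.  The exact solve (`exact_fixation_oracle`) is kept as
  an independent validator for N ≤ 5000: fixation probabilities by a
  banded harmonic solve, conditional absorption times by the Doob
  h-transform of the chain.
* **Conditional fixation time.** E[T | fix] = (2 ln N − ln i)/s in
  cell-division units.  Two conventions required a decision:
  * the formula is read as (2·ln N − ln i)/s, **not** 2·(ln N − ln i)/s;
    only the former reproduces the published ages (e.g. 4.87 vs 4.66 yr at
    s = 0.1);
  * divisions are converted to years at 365/4 = 91.25 divisions/yr (one
    division per 4-day CMP cycle).  A round "90 divisions per year" is
    sometimes quoted for the same system; 91.25 reproduces the published
    ages to ≤0.2% whereas 90 leaves ~1.6% error, so 91.25 is the default
    and both are configurable.
* **Adult pool.** N = 1.98×10⁸ cells/kg × 75 kg = 1.485×10¹⁰ (named
  constant `N_ADULT`).
* **Rounding.** Printed mutant counts round half-away-from-zero; the
  *unrounded* count feeds the time formula and the mutation-rate inversion
  (this matches the published table better; both modes are available).
* **s = 0.** The neutral limit i/N is returned with a log note rather than
  raising, so sweeps crossing zero do not crash.
* The stochastic simulator samples the embedded jump chain (up-moves with
  probability r/(1+r), geometric holding times), which is exactly
  equivalent in law to stepping the chain and much faster.

## 2. Fetal expansion (`scnclone.expansion`)

A time-continuous branching process: N₀ founder cells (default 1) divide
with exponential interdivision times (rate λ, default 0.25/day); each
wild-type division yields one mutant daughter with probability μ; mutants
breed true and are neutral during expansion.  Expected counts:
W(t) = N₀e^{(1−μ)λt}, i(t) = N₀(e^{λt} − e^{(1−μ)λt}); at final size N the
expected mutant count is N − N₀^μ N^{1−μ} ≈ μ N ln N.  The approximation
drops the founder correction ln N₀/ln N, so it is used (and inverted) with
N₀ = 1.

* **Birth pool convention.** The mutation-rate inversion targets the pool
  at birth.  The published rates are reproduced (≤1%) by
  N_b = 1.98×10⁸ × 3 kg = 5.94×10⁸ cells, not by the 5-kg infant-weight
  convention also mentioned in the source material (which would give
  ≈1.17×10⁻⁸ instead of 2.01×10⁻⁸ at s = 0.005).  Both constants are
  provided; 3 kg is the default calibration.
* **Samplers.** The exact simulator steps the Yule-embedded division
  sequence (feasible to ~10⁶ cells).  The large-N sampler thins mutation
  events (Poisson with founding sizes uniform over divisions) and draws
  each clone's final size from the beta-binomial Pólya-urn law
  (1 + X, X | p ~ Binomial(N−k−1, p), p ~ Beta(1, k) for a clone founded
  at population size k+1); the two agree distributionally
  (Kolmogorov–Smirnov) at overlapping scales.
* **Heavy tails.** Clone sizes are Luria–Delbrück distributed: finite
  samples systematically miss jackpot clones, so sample means sit a
  seed-dependent factor ~2–4 *below* μ N ln N even at thousands of
  replicates, while medians are stable.  Tests compare like-for-like
  finite samples or use factor bands on the mean, never tight bands.

## 3. Age-calibrated hematopoiesis (`scnclone.hematopoiesis`)

Two proliferating compartments, HSC (P) and CMP (C), with expectation
equations

    dP/dt = (2c(t) − 1)·a(t)·P
    dC/dt = 2(1 − c(t))·a(t)·m·P + (2d(t) − 1)·b·C
    βG(t) = 2(1 − d(t))·b·C(t)

where a = 1/T_P(t) is the HSC proliferation rate, b = 0.25/day the CMP
rate (4-day cycle), c and d self-renewal probabilities, and m = 1/4 the
granulocyte-lineage share of committed flux.  The exact published equation
system for this compartment structure is not available; this standard
self-renewal/differentiation reconstruction is a declared design choice,
isolated behind `integrate_compartments` and unit-tested against
closed-form solutions with frozen coefficients.

* **Calibration.** Body weight follows a monotone PCHIP curve through
  typical pediatric weights anchored at (0 d, 3.4 kg) and (18 yr, ~75 kg)
  — a stand-in for the exact published growth formula, whose constants are
  unavailable; the curve is pluggable.  The pooled count tracks
  1.98×10⁸ cells/kg of body weight; given a log-linear HSC slowing profile
  T_P from 2.5 d at birth to 280 d in adults (telomere-based estimates of
  adult HSC replication ~once per 40 weeks), c(t) and d(t) are solved
  pointwise in closed form and the ODEs re-integrated as a round-trip
  check (max tracking error < 1%, measured ~3×10⁻⁷).
* **Prenatal window.** Marrow hematopoiesis runs from −90 d to birth; the
  pool ramps geometrically from a founding count (default 10 cells) to the
  birth pool, consistent with the branching expansion.
* **HSC share.** The HSC fraction of the pool is not published; default
  10⁻³.  Downstream simulations consume only C(t), which moves by <2%
  when the fraction changes tenfold (tested).
* b is constant by default; the schedule accepts a callable b(t).

## 4. Hybrid takeover engine (`scnclone.takeover`)

The comprehensive model runs Moran dynamics on N(t) = C(t) with recurrent
mutation (probability μ per wild-type division) and a selection step
s(t) = 0 → s at the G-CSF start age (182.5 d; a ramp is configurable but
off by default).  Mutant influx from the HSC compartment is disregarded.
Per-cell simulation at N ~ 10¹⁰ is infeasible; the engine is:

* **Stochastic phase** (mutant count M < 10⁴): tau-leaping (default step
  1 day) of the continuous-time Moran rates
  up = b(1+s)M(N−M)/((1+s)M+N−M) + gM, down = bM(N−M)/((1+s)M+N−M),
  with g = d ln N/dt, plus Poisson influx μ·(b+g)·(N−M).  Neutral lineages
  are exactly critical at constant N and track N(t) otherwise; before
  birth turnover is zero and divisions occur at the expansion rate g,
  matching the branching model.
* **Deterministic phase** (M ≥ 10⁴): drift is negligible, and the mutant
  fraction follows df/dt = s(t)·b·f(1−f) + μ·b·(1−f) (RK4).  The
  replacement-age distribution shifts by <5% when the hand-off threshold
  moves across 10³–10⁵ (tested).
* **Replacement** is defined as mutant fraction ≥ 0.99: the final few
  wild-type cells of a 10¹⁰ pool take a biologically irrelevant extra time
  to disappear.  With recurrent mutation fixation is certain; only timing
  is random.
* **Validation.** At constant N = 1000 the engine reproduces the
  absorbing-chain oracle's fixation probability (3-SE band) and
  conditional fixation time (within 10%); with s = μ = 0 the mean count is
  a martingale (3-SE band).
* **Results at the study parameters.**  Replacement at 13 years with
  μ = 2.5×10⁻⁹ requires s ≈ 0.017 (20 replicates/evaluation, bisection
  with common random numbers); the required s decreases monotonically
  across the (4 yr, 10⁻⁹), (13 yr, 2.5×10⁻⁹), (22 yr, 5×10⁻⁹)
  combinations and is roughly half the proof-of-principle value — the
  growing pool and recurrent mutation make takeover easier, so less
  selection is needed.
* **Known tension.**  The mean mutant count at age 1 year scales as
  ≈ μ·(N ln N + b·∫N dt): recurrent postnatal mutation at the constant
  CMP turnover b contributes ~91 divisions per cell-year and therefore
  dominates the fetal term roughly tenfold.  An often-quoted 10¹–10³
  count range for μ = 10⁻⁹–10⁻⁷ corresponds to the fetal contribution
  alone (the count at birth); the model reports both, and the
  corresponding acceptance test is intentionally left failing at the two
  upper rates rather than weakening the model or the band (see the test
  docstring).  An age-varying CMP cycle time could reconcile the two but
  its values are not available to calibrate.

Problem sizes used by the test suite and examples (reduced-scale choices
of this package): ≤3000 replicates per stochastic comparison, N ≤ 1000 for
exact-chain cross-checks, 15–40 replicates per nomogram cell.

## 5. Selection inference (`scnclone.selection`)

* **Cell-cycle chain.**  With constant interdivision time T, G1/G0
  residence T₁ and division efficiency α, growth is exponential at
  λ = ln(2α)/T and φ = (1−e^{−λT₁})/(1−e^{−λT}).  The inverse is
  ψ = −ln[1 − φ(1 − (2α)⁻¹)]/ln(2α); attributing the entire
  interdivision-time difference to G1 shortening gives
  Δ = T(ψ−ψ*)/(1−ψ*), λ* = ln(2α*)/(T−Δ) and s = λ*/λ − 1.  Both fraction
  layouts in the typeset source are ambiguous; the readings above are
  fixed by requiring the worked example (φ = 0.70 → ψ = 0.621;
  Δ = 0.503) to reproduce, which they do exactly.  The API accepts either
  φ- or ψ-pairs per line because the published worked example's
  ψ* = 0.567 corresponds to φ* ≈ 0.65, not the quoted φ* = 0.66 (which
  gives ψ* = 0.578) — an internal inconsistency of the source data that
  the package surfaces rather than resolves.
* **Hill fitting.**  y = y₀ + a(ln x − c)ⁿ/((ln x − c)ⁿ + bⁿ), fitted
  jointly for both lines with a single shared y₀ (one optimisation, not
  two fits averaged), by bounded least squares multi-started over a grid
  of log-dose offsets and exponents; n is bounded in (0, 50].  The b/c
  parameterisation is ridge-like: under noise, individual parameters can
  trade off while the fitted response stays put, so the noisy-data test
  asserts curve agreement rather than parameter agreement.
* **Rank tests.**  One-sided Wilcoxon–Mann–Whitney on the raw replicate
  points, split at 0.1 ng/ml (or at the fitted crossing): mutant >
  reference above, reference > mutant below.  Exact enumeration for
  untied strata with ≤10 points per group; midrank normal approximation
  *without* continuity correction otherwise, so identical samples give
  exactly p = 0.5.  A fully degenerate (all-equal) stratum returns 0.5 by
  convention.

## 6. Synthetic assay generators (`scnclone.assays`)

The dose-response generator draws triplicate absorbance values around the
published Hill-curve coefficients (shared y₀ = 0.349) with independent
Gaussian noise (default SD 0.02 a.u.) on a 13-point log grid spanning
10⁻³–10³ ng/ml.  The G1/G0 series generator relaxes exponentially from a
starvation-arrest level (85%) to line-specific asymptotes (default
separation 6.05 percentage points, the 100 ng/ml condition; 4.28 for
50 ng/ml) with binomial counting noise from 10⁴ gated cells per sample.

What these generators emulate — and what they do not: they reproduce the
mean structure, replicate noise and effect directions of the assays, so
closed-loop tests (generate → fit/estimate → recover) validate the
estimators' correctness and power at realistic noise.  They do not model
plate effects, pipetting drift, FlowJo gating error, dose-dependent
variance or cell-line heterogeneity, so passing tests say nothing about
robustness to those real-data pathologies.

## 7. Known limitations

* The compartment ODE reconstruction and the growth curve approximate
  unavailable published parameterisations; comprehensive-model outputs are
  therefore order-of-magnitude calibrated (factor-2 agreement on the
  13-year selection coefficient), not digit-matched.
* Only a single acquired driver is modelled: no multi-mutant competition,
  no sAML transformation, no G-CSF pharmacokinetics.
* Selection acts only on the CMP compartment from a fixed switch-on age;
  dose-dependence of s (clearly present in the dose-response data) is not
  propagated into the population model.
* The tau-leap step (1 day) is coarse relative to the CMP cycle; the
  cross-engine validation bounds the resulting bias at small N, and the
  deterministic phase is insensitive to it.
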