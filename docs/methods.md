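# Methods

## Microtubule dynamics model

Dynamic instability is generated by a three-state continuous-time Markov
chain over growth, shrink and pause — the minimal model consistent with the
catastrophe/rescue definitions used for astral microtubules (catastrophe:
growth or pause → shrink; rescue: shrink or pause → growth). Length changes
at +v_g (µm/min) in growth, −v_s in shrink and 0 in pause; dwell times are
exponential with hazards λ_GS, λ_GP, λ_SG, λ_SP, λ_PS, λ_PG (min⁻¹). The
initial state is drawn from the chain's stationary distribution unless
overridden; the initial length defaults to 0.9 µm (a typical astral
microtubule length in pre-anaphase yeast).

**Zero-length boundary.** A microtubule that shrinks to zero renucleates: the
simulator forces a transition to growth at the hitting time. This keeps
traces full-length for statistics, matching the persistence of astral
microtubules in vivo; trace termination at zero is available as a flag.
Forced renucleations are flagged on the exact path and excluded from the
chain-level rescue count — they are boundary artifacts, not stochastic
rescues. (The classifier, which sees only the sampled lengths, will still
score a sharp V at zero as a rescue if both legs pass the event thresholds,
exactly as a human tracing kymographs would.)

**Sampling and noise.** The exact piecewise-linear path is sampled at 4 s
(or 5 s) intervals for 600 s and independent Gaussian noise (default
SD 0.05 µm, the scale of sub-pixel localization error in yeast imaging) is
added per sample, then lengths are clamped at zero. Both the path and the
noise derive from one seeded generator per trace, so every artifact is
bit-reproducible from its seed.

## Solving hazards from published summary statistics

Published per-condition tables report observable statistics, not hazards:
mean phase durations (τ_G, τ_S, τ_P, in seconds), catastrophe frequency
f_cat (events per minute of growth + pause time) and rescue frequency f_res
(events per minute of shrink + pause time). In the stationary regime these
pin down the chain as follows. The three mean dwells fix the total exit
rates (λ_G = 60/τ_G etc.). Writing the embedded chain's visit rates per
growth entry — u_S entries into shrink, u_P into pause — the frequency
definitions give the closed form

    u_P = (1/f_res − τ_S f_cat τ_G) / (τ_P (1 + τ_S f_cat)),
    u_S = f_cat (τ_G + τ_P u_P),

(durations in minutes), after which the branch fractions a = P(G→S),
b = P(S→G) follow from flow balance given c = P(P→G), the fraction of pause
exits that resume growth. c is the one genuinely free degree of freedom;
it defaults to ½ (a pause equally likely to resolve either way) clamped
into its feasible interval. Residuals of the frequency constraints are
verified against the stationary distribution to 1e-8; infeasible targets
fall back to a bounded least-squares fit and are flagged. With the pause
state disabled the chain is two-state and λ_GS = f_cat, λ_SG = f_res
exactly (mean dwells are then implied by the frequencies and the
duration targets are ignored).

At the wild-type reference values (τ_G = 46 s, τ_S = 27 s, τ_P = 18 s,
f_cat = 0.90 min⁻¹, f_res = 1.5 min⁻¹) the solution is exact, and forward
simulation of 500 traces recovers both frequencies from the exact paths
within three standard errors (pooled f_cat 0.875, f_res 1.535).

## Phase classification

The classifier reproduces the published event definitions as a
deterministic, greedy procedure on the sampled trace:

1. inter-sample displacements are signed; isolated single-sample sign flips
   smaller than the pause flatness (0.25 µm) are absorbed into their
   context, and maximal same-sign runs become candidate monotone phases;
2. a candidate is promoted to assembly/disassembly when its net length
   change is ≥ 0.5 µm **and** the magnitude of the linear correlation of
   length against time over the run is ≥ 0.85;
3. remaining stretches are scanned left-to-right for windows of ≥ 4 samples
   whose total excursion (max − min) is ≤ 0.25 µm; these become pauses;
4. everything else is undetermined;
5. catastrophes/rescues are recorded between consecutive classified phases,
   bridging undetermined gaps of ≤ 2 interior samples (so one or two noisy
   samples cannot erase an event); longer gaps sever adjacency.

The published fit-quality threshold is stated as a "coefficient of
variation ≥ 0.85"; a conventional CV (SD/mean) cannot be thresholded this
way for a trending signal, so it is implemented as the linear correlation
magnitude and the config key is named `min_fit_quality` to stay
interpretation-neutral. The pause flatness (0.25 µm, half the event
threshold) is likewise this package's operationalization of "without
significant change"; no published number exists for either.

Phases are inclusive sample-index ranges in which consecutive phases share
their boundary sample, so phase durations telescope exactly to the trace
duration (the tiling invariant asserted by the tests). Greedy run-merging
was chosen over global change-point optimization for transparency and
determinism; on noiseless piecewise-linear traces whose legs exceed the
thresholds, the segmentation provably equals the generating structure
(boundaries within one sample, event counts exact), which bounds the cost
of the greedy choice.

## Dynamics statistics

Per microtubule: rates are duration-weighted mean slopes over phases of a
kind (disassembly reported as positive speed); durations are per-phase
means; mean length is the average of all samples; frequencies divide event
counts by the summed time in the relevant states, in minutes, with
undetermined time excluded from denominators (undetermined samples are by
definition none of the three states). Zero-denominator frequencies are
marked undefined and dropped per-statistic during aggregation, never
imputed. Cohorts report mean ± SEM across microtubules (frequencies are
averaged per microtubule, not pooled over events, matching how such tables
are built); fewer than five distinct cells triggers a warning. Because both
"per cell" and "per microtubule" groupings are defensible, the long-format
table carries cell and microtubule identifiers so either aggregation can be
formed. Condition comparisons use Welch's unequal-variance two-sample
t-test — the robust default when cohort sizes differ; the published
analyses state only "t-test". Its type-I error is calibrated (0.03–0.07 at
α = 0.05 under the null in 1000 simulated repeats).

## What the round trip can and cannot recover

The acceptance-level round trip — simulate at a published condition row,
classify, summarize — is an honest test of the *whole* observation chain,
and its results separate cleanly:

* recovered **assembly rate** is within 5% of v_g, and the noiseless
  **kinetics and mass** tracks recover their ground truth to 1e-6 and
  exactly, respectively;
* **event frequencies and pause duration are attenuated**: at the wild-type
  values the classifier recovers f_cat ≈ 0.48 vs 0.90 min⁻¹, f_res ≈ 1.07
  vs 1.5 min⁻¹, pause duration ≈ 24 s vs 18 s, and disassembly rate ≈ 2.55
  vs 3.06 µm/min (200 traces, default noise).

The attenuation is intrinsic to the published measurement procedure, not an
estimator defect. The 0.5 µm net-change threshold censors shrink phases
shorter than ~10 s (31% of shrink dwells at τ_S = 27 s) and growth phases
shorter than ~21 s (37% at τ_G = 46 s); every catastrophe or rescue adjacent
to a censored phase is lost, and undetermined time is excluded from the
denominators only partially compensates. The 4-point pause minimum truncates
the pause-duration distribution from below (for an exponential 18 s dwell,
E[T | T > 12 s] = 30 s). Short shrink phases also carry proportionally more
boundary-sample dilution, biasing the duration-weighted disassembly speed
down. Even noiseless simulation recovers f_cat at −48%, confirming that
measurement noise is not the cause. Recovering the chain parameters to a
tight tolerance would require inverting this observation operator (fitting
the chain to the *classified* statistics), which is deliberately out of
scope: the hazard solver maps published statistics to chain parameters via
the stationary identities, treating the published numbers as chain-level
truth. Users comparing conditions are unaffected — the attenuation applies
to all conditions alike — but absolute frequencies read off classified
traces sit below the generating chain's, here by ~30–50%, and the test
suite documents the measured gaps rather than hiding them.

Chain-level recovery (from the exact simulated paths rather than classified
traces) is unbiased and is what the generator's own tests assert.

## GTPase kinetics

The standard curve is an ordinary least-squares line (absorbance per µM
phosphate); absorbances convert to phosphate as (A − intercept)/slope,
clamped at zero with a log entry per clamped value, and to rates assuming
linear accumulation over the 90-min incubation. The Michaelis–Menten fit is
unweighted nonlinear least squares (a weighting hook is exposed),
initialized at V_max⁰ = max observed rate and K_m⁰ = the interpolated
substrate level at half of V_max⁰, run as a bounded trust-region search on
rate-normalized data followed by a short Gauss–Newton polish. The
normalization and polish exist for numerics: they condition the problem and
pin the stationary point to ~1e-13, making the fit reproducible and exactly
scale-equivariant (rates × c ⇒ V_max × c, K_m unchanged) instead of
wandering on the float-flat cost plateau. Standard errors come from the
Jacobian at the optimum; non-convergence is flagged, not raised; a fit
whose K_m falls outside the titration span is logged as poorly constrained.

The default synthetic design matches the standard assay: 1 µM enzyme, ten
GTP levels spanning 0–800 µM, 3% multiplicative rate noise. A 90-min
endpoint at low [GTP] is not a true initial rate: with 1 µM enzyme and
k_cat ≈ 1.9 min⁻¹, micromolar substrate is substantially depleted. The
generator's `depleting` mode integrates dS/dt = −V_max·S/(K_m+S) over the
incubation and reports the endpoint-averaged rate, quantifying that bias
(largest at low substrate, vanishing at saturation); the fitting stage
deliberately does not correct for it, mirroring standard practice, and the
recovery tests use the ideal initial-rate mode.

The built-in reference parameter sets use the running-text k_cat values
where text and table differ at the last digit (1.85 vs 1.88 min⁻¹ for the
ternary reaction; K_m 371 µM from the table for the Q73L mutant); the
recovery tolerance (10% on the median of 20 replicates) is agnostic to the
discrepancy.

## Complex mass accounting

Predicted masses are exact integer-weighted sums in daltons; kilodalton
rounding happens only at display. Stoichiometry inference enumerates every
composition with per-subunit copy numbers up to `max_copies`, keeps those
within `tolerance_sd` (default 2) standard deviations of the measured mass,
and ranks by absolute residual with a lexicographic tie-break — brute force
by construction, so the property tests only need to assert the admissible
set and the ranking. Two tubulin-dimer presets ship: the 110 kDa value used
in predicted complex masses and the 100 kDa light-scattering value for the
free dimer; which to use is the caller's choice since the source convention
is not stated.

## Pipeline and reproducibility

A run configuration (plain dict or YAML) fixes every stage and one master
seed. Per-condition seeds derive by CRC-32 hashing of the condition label
with the master seed, so adding or removing a condition never perturbs the
others; per-trace seeds spawn from the condition seed via numpy's
SeedSequence. Outputs are tab-delimited text with unit-bearing headers, and
a manifest records the config hash and every derived seed; reruns with the
same config and seed are byte-identical (asserted by the tests).

## Problem sizes

Defaults are chosen as desk-scale reproductions: 200 traces of 600 s at 4-s
sampling per dynamics condition, 10 substrate levels and 20 replicate
titrations per kinetics condition, compositions up to 2 copies per subunit.
The full demo completes in about one second; the test suite, including the
1000-trace tiling sweep and 1000-repeat calibrations, in well under a
minute.

## Known limitations

* The generator's exponential dwells and additive Gaussian noise are
  idealizations; real traces show aging of catastrophe rates, correlated
  tracking errors and drift that the synthetic module does not emulate, so
  passing recovery tests bound estimator behaviour under the model, not
  under every imaging artifact.
* Event timing is quantized to the sampling interval; no sub-interval
  localization is attempted.
* The classifier-level frequency attenuation described above means absolute
  catastrophe/rescue frequencies are systematically conservative relative
  to the generating process.
* No per-cell mixed-effects modelling, no survival analysis of phase
  durations, no global shared-parameter kinetics fits.
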