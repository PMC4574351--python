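# tbckit

Quantitative analysis for tubulin-cofactor chaperone experiments — the TBC-DEG
system (the heterotrimer of tubulin cofactors TBCD, TBCE and the Arl2 GTPase),
its GTPase-activating protein TBCC, and the microtubule phenotypes that follow
when the chaperone cycle is perturbed in budding yeast.

The package covers the three quantitative tracks of such a study, each paired
with a synthetic-data generator carrying known ground truth so every estimator
can be validated by round-trip parameter recovery:

1. **Microtubule dynamic instability.** Astral-microtubule length-vs-time
   traces (sampled every 4 or 5 s for ~10 min) are segmented into assembly,
   disassembly and pause phases. An assembly/disassembly event is a continuous
   phase with a net length change ≥ 0.5 µm and a linear fit quality ≥ 0.85; a
   pause lasts at least four data points without significant length change. A
   *catastrophe* is a transition from assembly or pause into disassembly, a
   *rescue* from disassembly or pause into assembly. Per-microtubule
   frequencies divide event counts by the time available for the event
   (catastrophes over assembly + pause time, rescues over disassembly + pause
   time); conditions are compared with Welch's t-test. The generator is a
   three-state continuous-time Markov chain (growth at +v_g, shrink at −v_s,
   pause at 0, exponential dwell times, renucleation at zero length) solved so
   that its stationary statistics match a published condition row.

2. **GAP-stimulated GTPase kinetics.** Malachite-green assay analysis: a
   0–5 µM phosphate standard line calibrates 621-nm absorbances, endpoint
   phosphate over the 90-min incubation gives hydrolysis rates, and GTP
   titrations (0–800 µM) are fitted to the Michaelis–Menten model
   `v = V_max·S/(K_m+S)` with `k_cat = V_max/[E]` (1 µM enzyme in the standard
   design, so k_cat in min⁻¹ equals V_max in µM/min). Conditions are compared
   as percent change in k_cat against a reference reaction.

3. **Complex stoichiometry.** Exact mass accounting for subunit compositions
   (e.g. TBCD + TBCE + Arl2 = 197,972.0 Da ≈ 198 kDa) and brute-force
   inference of integer stoichiometries consistent with a measured mass
   (e.g. from SEC-MALS) within a stated tolerance.

## Worked example

The built-in demo simulates three dynamics conditions, five GTPase reactions
and the mass bookkeeping for the chaperone complexes, writing tab-delimited
reports to an output directory:

```sh
tbckit demo --seed 1 --out-dir demo_out
```

The kinetics report it prints (rounded):

```
                 condition   Km_uM  Km_se  kcat_per_min  kcat_se  converged  kcat_ratio  percent_decrease
      TBC-DEG:TBCC:tubulin  99.064  5.256         1.828    0.025       True       1.000             0.000
              TBC-DEG:TBCC  89.244  7.733         0.751    0.016       True       0.411            58.913
TBC-DEG:TBCC-R186A:tubulin  40.561  3.982         0.544    0.010       True       0.297            70.251
TBC-DEG:TBCC-dLoop:tubulin  35.059  2.900         0.343    0.005       True       0.188            81.236
 TBC-DEG-Q73L:TBCC:tubulin 335.684 33.347         0.481    0.021       True       0.263            73.684
```

Each row is one simulated titration fitted from scratch: the full ternary
reaction turns over fastest (k_cat ≈ 1.85 min⁻¹ ground truth), removing
tubulin or mutating the TBCC arginine finger (R186A) or acidic loop (ΔLoop)
cuts k_cat by 59–81%, and the GTP-locked Arl2 mutant (Q73L) both slows
turnover and raises the apparent K_m — the signature of a broken GAP cycle.

And the mass report:

```
             complex  predicted_da  predicted_kda  measured_kda  measured_sd_kda  residual_kda
             TBC-DEG      197972.0            198         215.0             10.0      -17.0280
     TBC-DEG:tubulin      307972.0            308         310.0             10.0       -2.0280
TBC-DEG:TBCC:tubulin      342017.4            342         335.0             10.0        7.0174
```

A 310 ± 10 kDa light-scattering mass is consistent with exactly one chaperone
core binding one αβ-tubulin dimer (308 kDa predicted); adding TBCC brings the
predicted ternary complex to 342 kDa.

The same steps are available as library calls
(`tbckit.simulate_titration`, `tbckit.fit_mm`, `tbckit.classify_trace`,
`tbckit.summarize_condition`, `tbckit.infer_stoichiometry`, ...) and as the
CLI subcommands `simulate-traces`, `classify`, `summarize`, `compare`,
`simulate-gtpase`, `fit-kinetics` and `predict-mass`.

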