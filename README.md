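# thermoshred

Quantitative pipeline for the thermal biology of competing freshwater
shredders: the native amphipod *Gammarus pulex* and the invasive "killer
shrimp" *Dikerogammarus villosus*.  Amphipod shredders drive leaf-litter
decomposition in streams, so whether an invader that displaces the native
processes more or less detritus — and how that balance shifts with water
temperature — matters for whole-ecosystem energy flow.  `thermoshred` is
aimed at quantitative ecologists who want the full analysis chain as
tested, reusable, seedable code.

The package implements four linked analyses, exercised end-to-end on a
synthetic-data generator with known ground truth:

1. **Thermal preferenda (acute method).**  Per-individual median selected
   temperature on a 4–24 °C gradient track → acute preferendum per
   acclimation group (mean ± SE) → final preferendum as the intersection
   of the acute preference line `pref = a + b·T_acc` with the 1:1 line,
   `a/(1−b)`, with a parametric-bootstrap CI.  Control-trial spatial
   uniformity is tested by chi-squared over 10 cm track bins, and
   candidate preference models are ranked by AICc with Akaike-weight
   model averaging (ΔAICc < 4).
2. **Shredding efficiency.**  Dry leaf mass consumed per amphipod-day,
   with moult exclusion and a control-leaching discount rule; PCA
   body-size index; species × temperature two-way ANOVA.
3. **Metabolic theory (Arrhenius).**  Temperature standardised as
   `x = 1/kT_c − 1/kT` (k = 8.62×10⁻⁵ eV/K, T_c = 288.15 K); OLS of
   ln(mean shredding rate) on `x` estimates the activation energy E_a
   (eV) with 95% CI, classified against the 0.60–0.70 eV
   consumer–resource band; species compared by ANCOVA.
4. **Preference–performance coupling and projection.**  Habitat use per
   ±1 °C temperature zone vs per-capita performance, fitted as
   `shredding ~ α + β/use` by orthogonal non-linear least squares (both
   axes measured with error); population shredding capacity
   `rate × mean mass × survival × 100` across temperature, with Pearson
   capacity–temperature trends and species ratios.

See `docs/methods.md` for model details, defaults, and limitations.

## Worked example

Run the whole synthetic study (simulate → preference → shredding → mte →
couple → project) from the command line:

```sh
thermoshred reproduce --seed 42 --outdir demo/
```

which writes 18 CSV tables plus `ground_truth.yaml` and
`run_metadata.json`, and prints the headline estimates:

```
    species  final_preferendum_c  intercept_c     slope    ci_low   ci_high
D. villosus            14.172323    15.784992 -0.113790 13.959498 14.396691
   G. pulex            13.329891    11.934963  0.104647 13.287701 13.371513
    species      dataset  intercept  activation_energy_ev  r_squared mte_band
   G. pulex size-matched  -4.454652              0.224275   0.991961  outside
   G. pulex     all-data  -4.457921              0.218315   0.996369  outside
D. villosus size-matched  -5.791969              0.688502   0.999427   within
D. villosus     all-data  -5.793204              0.681310   0.999894   within
```

Reading the output: the generator's preference lines intersect the 1:1
line at 13.4 °C (*G. pulex*, preference rising with acclimation) and
14.3 °C (*D. villosus*, falling), and the pipeline recovers 13.33 and
14.17 °C from one seeded data set.  Likewise the generating activation
energies (0.21 and 0.68 eV) are recovered as 0.22 and 0.68 eV; only the
invader's estimate sits inside the metabolic-theory band, marked
`within`.  Every stage is also callable as a library function
(`thermoshred.run_pipeline`, `arrhenius_fit`, `onls_fit`, …) or as an
individual subcommand (`simulate`, `preference`, `shredding`, `mte`,
`couple`, `project`, `validate`) operating on the CSV tables.

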