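# embryoscope

Quantitative pipeline for cephalopod embryo ecophysiology:

- **respirometry** — closed-chamber oxygen traces → per-embryo metabolic
  rates: best linear 5–10 min segment (OLS, exhaustive window search),
  blank-vial correction, the MO2 equation
  `MO2 = (O2_A − O2_B)·(V/t)/M`, and the Q10 temperature coefficient.
- **scope** — loess (tricube, degree 2) MO2–weight fits at a low (TIMR-min,
  11 °C) and a high (TIMR-max, 30 °C) exposure temperature; thermal
  metabolic scope `TMS = high − low`, factorial scope `FMS = high / low`,
  and TMS curve features (peaks, terminal trend).
- **growth** — exponential stage–weight models `W = a·e^(b·stage)` for eggs
  and embryos (log-linear OLS or nonlinear LS), with flagged back-prediction
  of unmeasurable early-stage weights.
- **biomarkers** — oxidative-stress analyte profiles (SOD, CAT, GST, GSH,
  LPO, PO) across ovary / un-spawned eggs / embryo stages: normalization,
  mean ± SD summaries, bootstrap fold-ratios.
- **qpcr** — standard-curve amplification efficiency
  `E = −1 + 10^(−1/slope)`, reference-gene stability ranking (geNorm-style M
  + ΔCt SD, combined by geometric mean of ranks), Hellemans
  efficiency-corrected relative quantities (`RQ`, `NF`, `NRQ = RQ/NF`,
  reported on the ln scale), and one-way stage/phase comparisons.
- **synthetic** — seeded generators for every pipeline input with known
  ground truth (true MO2 per vial, true growth parameters, true
  efficiencies and fold-changes, designed biomarker profiles), used by the
  test suite for end-to-end parameter-recovery checks.

## CLI

All commands live under a single `embryoscope` entry point:

```bash
# generate a synthetic dataset (all inputs + ground truth)
embryoscope simulate --out data/ --seed 42            # optional --config sim.yaml

# oxygen traces -> metabolic rates
embryoscope respiro --traces data/traces.csv --cohort data/cohort.csv \
    --out rates.csv --rejects rejects.csv

# loess fits + TMS/FMS curve and features
embryoscope scope --rates rates.csv --low LMR --high HMR --span 0.5 --out scope/

# exponential stage-weight model with early-stage back-prediction
embryoscope growth --cohort data/cohort.csv --subject embryo \
    --predict 6,7,8,9 --out model.json

# qPCR: efficiencies, reference stability, relative expression
embryoscope qpcr efficiency --in data/dilution.csv --out efficiencies.csv
embryoscope qpcr stability  --in data/cq.csv --out stability.csv
embryoscope qpcr express    --in data/cq.csv --efficiencies efficiencies.csv \
    --refs TufM,GPAM --out expression.csv

# biomarker profiles and ovary/egg fold-ratios
embryoscope biomarkers --in data/biomarkers.csv --out profiles.csv --ratios OV:USE
```

## Notes

- The reference-gene stability ranking approximates the closed RefFinder
  web tool by two of its published components (geNorm M and ΔCt SD).
- Embryo-displaced chamber volume is derived from wet mass assuming tissue
  density 1.0 g mL⁻¹.
- File formats are plain CSV/JSON/YAML; see `embryoscope.io` for the exact
  column dialects.
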