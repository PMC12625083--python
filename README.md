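# cuidose

Benefit–risk dose selection for antibody–drug conjugates (ADCs) from
**summary-level** clinical-trial data.

Published trials of drugs like trastuzumab emtansine (T-DM1) and
trastuzumab deruxtecan (T-DXd) report arm-level means: concentration–time
points, exposure metrics (Cmax, Cmin, AUC), response rates and toxicity
counts.  `cuidose` turns a table of such arms into a dose recommendation:

1. **Population PK by meta-analysis** — a two-compartment IV-infusion
   model with correlated log-normal between-study variability on clearance
   (CL) and central volume (Vc), fitted to the summary concentrations by a
   Laplace-approximated marginal likelihood.  The residual SD for an arm
   of n subjects is `a + (b/√n)·f`: means of larger trials are less noisy.
2. **Exposure simulation** — 1000 replicates per dose level of the
   escalation grid, drawn from the fitted variability (or the posterior
   given an arm's data) and pushed through the closed-form model at the
   median body weight.
3. **Exposure–response** — weighted quasi-binomial logistic fits
   `logit p = β₀ + β₁·x` of objective response (ORR) and composite
   dose-limiting toxicity (DLT) on a PK metric, with prior weights √n, per
   development-stage scenario (phase I only / phases I–II / all phases).
4. **Clinical utility index** —

       CUI(x) = w·p_orr(x) + (1−w)·(1−p_dlt(x)),

   averaged over each dose's exposure span; starting from the lowest dose,
   escalate while the relative improvement in average CUI meets a
   threshold τ.  Scans over w (10–90%) and τ (2.5–20%) summarise how the
   recommendation responds to the efficacy–safety trade-off.

A synthetic-data module generates datasets with the same statistical
structure (study-level random effects, √n-shrinking noise, binomial
outcomes on a logistic exposure–response, dose-escalation phase-I studies,
patchy reporting), so the whole pipeline is testable offline.

## Worked example

```bash
cuidose run-all --drug TDM1 --seed 7 --out-dir run_tdm1
```

simulates a 20-study T-DM1-like dataset, fits the PK model, simulates
7 × 1000 exposure replicates, fits the ER models per scenario and scans
the CUI grids.  On this run the manifest reports:

```
"fit_pk": {"convergence": true, "n_arms": 34}
"simulate_exposures": {"n_records": 21000, "weight_kg": 69.4}
"cui": {"n_settings": 3864, "skipped": []}
```

and `run_tdm1/pk_fit.json` contains the fitted parameter table:

```
"Clearance (L/day)":                  {"estimate": 0.771, "rse_pct": 8.8}
"Central volume of distribution (L)": {"estimate": 3.157, "rse_pct": 4.7}
"BSV clearance":                      {"estimate": 0.454, "rse_pct": 16.1}
```

— the generating values are CL 0.809 L/day, Vc 3.283 L, ω_CL 0.334, so
the fit recovers them from 34 noisy summary arms within the reported
precision.  `cui_selections.csv` holds one selected dose per
(scenario, τ, w): on this dataset the sigmoid response is flat across the
first escalation step, so at τ = 10% every weight setting stops at the
0.3 mg/kg starting dose (high thresholds favour starting doses), while at
τ = 2.5% an ORR weight of 81% escalates all the way to 4.8 mg/kg.
`cui_selection_frequency.csv` shows 4.8 mg/kg selected in 18–21% of
weight settings at τ = 2.5% depending on scenario, and
`cui_median_weight.csv` reports a median ORR weight of 83% among the
settings that select it.  Each stage is also exposed separately
(`cuidose simulate`, `fit-pk`, `simulate-exposures`, `fit-er`, `cui`) and
as a library (`cuidose.mbma.fit`, `cuidose.cui.scan`, ...).

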