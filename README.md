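# ictaxis

Construction of an **Impulsivity–Compulsivity axis** from four self-report
questionnaires on the use/abuse of information and communication
technologies (ICT), with the downstream statistics and machine-learning
character predictors — plus a synthetic-cohort generator so the whole
analysis runs end to end without survey data.

The package is aimed at researchers and clinicians working with
behavioral-addiction screening batteries who want a reproducible,
scriptable implementation of the axis methodology: scoring, score
conditioning, axis banding, the accompanying nonparametric/Bayesian
statistics, and two-feature Gaussian-process character classifiers.

## The axis

Four instruments are scored: the short **UPPS-P** (20 items, five
impulsivity subscales), the **OCDUS-ICT** (12 items, three compulsivity
factors, items 6/12 reverse-keyed), the **PSI-20** (prefrontal symptoms)
and the **MULTICAGE-ICT** (five 4-item dichotomous screening scales; a
scale at ≥ 50% endorsement flags possible addiction signs). After linear
0–100 rescaling, Mahalanobis outlier exclusion (χ²₈, p < 0.001),
OLS residualization on age/education band codes and Z-standardization,

```
axis = 10 × ( mean(5 UPPS residual-Z) − mean(3 OCDUS residual-Z) )
```

Positive values mark the impulsive pole. Bands at ±10 / ±20 give five
character labels (high/moderate impulsivity, balance, moderate/high
compulsivity). Balance-band subjects are excluded and the rest, labeled
by axis sign, train two-feature classifiers — GPC with an RBF(1.0)
kernel on (PSI %, MULTICAGE %) and on (UPPS %, OCDUS %) — whose decision
regions are mapped over the feature plane and distilled into two
quadratic threshold curves.

## Worked example

```
$ ictaxis run-all --out demo_run --seed 42
done: n=802, axis mean 0.00, SD 8.61 -> demo_run/report.md
```

The run simulates the default cohort (n = 807, demographics and score
structure shaped like the reference survey sample), excludes 5 subjects
as multivariate outliers (Mahalanobis d² > 26.12), and reports — from
`demo_run/report.md`:

```
n = 807, p = 72 items, n/p = 11.21 (pass; minimum n = 720).
mean 0.00, SD 8.61, range [-26.25, 23.48], skewness -0.21, excess kurtosis -0.08.
Band counts: balance: 603, moderate_impulsivity: 96, moderate_compulsivity: 86,
high_compulsivity: 12, high_impulsivity: 5
- gpc_upps_ocdus (UPPS_total_pct x OCDUS_total_pct): n=199 (24.8% of cohort),
  split 159/40; gpc: 100.0%, ...
Distilled quadratic rule agreement with GPC: 99.5%.
```

Reading: the axis averages exactly 0 by construction (it is built from
mean-zero standardized residuals); its SD ≈ 8.6 and the ≈ 25% of
subjects outside the balance band reflect the calibrated trait loadings;
the UPPS/OCDUS classifier separates the two characters essentially
perfectly on synthetic data because the labels derive from the same
instruments' residualized scores. Individual predictions come from the
persisted decision grid:

```
$ ictaxis predict --run-dir demo_run --model gpc_upps_ocdus --upps 40 --ocdus 75
{ "p_compulsive": 0.7397, "label": "compulsive", "zone": "compulsive" }
```

A subject at OCDUS 75% is classified compulsive at moderate UPPS — high
OCDUS is decisive on its own, mirroring the decision-region structure.

Other subcommands: `simulate` (write a synthetic cohort's CSVs), `score`,
`axis`, `stats`, `report`; the library API (`ictaxis.*`) exposes every
stage directly, see `docs/methods.md` for the model and its assumptions.

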