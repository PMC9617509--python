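# ocuvegf

An ocular anti-VEGF PK/PD toolkit for preclinical scientists comparing
intravitreal VEGF inhibitors — built around the head-to-head rabbit
comparison of aflibercept (115 kDa trap), brolucizumab (26 kDa scFv), and
ranibizumab (48 kDa Fab).

It implements, as one tested pipeline:

- **Solution-equilibrium affinity** (kinetic exclusion / KinExA): the
  one-site homogeneous binding model — free inhibitor fraction from the
  1:1 site mass balance, `F = ½[(I−L−K_D) + √((I−L−K_D)² + 4·K_D·I)]` —
  fitted globally across titration curves at several constant inhibitor
  concentrations (N-curve analysis) with one shared K_D and a
  profile-likelihood 95% CI.
- **Cell potency**: four-parameter logistic IC50 fits,
  `y = bottom + (top−bottom)/(1+(c/IC50)^h)`, with Tukey all-pairs
  comparison of log-IC50s.
- **Ocular PK**: a minimal physiology-based anterior-elimination model —
  drug leaves the vitreous by diffusion (rate ∝ D ∝ 1/r_h, with
  hydrodynamic radius r_h ∝ MW^(1/3)) and clears via aqueous humor
  turnover, so the vitreal half-life scales with molecule size — plus
  noncompartmental analysis (linear-up/log-down AUC, best-adjusted-R² λz
  window, CL = dose/AUC, V_ss = CL·MRT) of destructive-sampling vitreous
  profiles with LLOQ censoring.
- **VEGF-challenge pharmacodynamics**: mass-action drug–VEGF–complex
  kinetics with species-specific ocular elimination, integrated in a fast
  quasi-equilibrium mode (full stiff ODE kept as a verification oracle);
  the readout is the AUC of free VEGF between challenge injection and the
  47 h observation, as a percent of a vehicle run.
- **Leakage exposure–response**: angiography scores dichotomized at ≥ 2,
  and the two-parameter logistic
  `p(x) = 1/(1+exp(−(x−x50)/slope))`
  linking percent free VEGF *x* to the probability of moderate-to-severe
  leakage, fitted by Bernoulli maximum likelihood, with exact
  back-calculation `x(p) = x50 + slope·logit(p)`.
- **A synthetic-study generator** reproducing the study conditions
  (duplicate KinExA curves at the published concentration designs, 7
  animals per group per time point, challenges at days 5/26/33/40/54/68,
  observation 47 ± 3 h, assay-specific LLOQs), so the entire chain runs
  with no external data.

## Worked example

`examples/05_leakage_model.py` generates the full synthetic cohort, fits
the leakage logistic (generating truth x50 = 70, slope = 17.31), and
back-calculates the exposure table:

```
observations fitted : 161 (7 excluded: vehicle week 10)
x50                 : 69.8 % free VEGF
slope               : 15.82 % per logit
in-sample accuracy  : 0.89
risk elbow (p=0.1)  : 35 % free VEGF

back-calculated free VEGF at requested probabilities:
  p = 0.2 ->  47.9 %
  p = 0.5 ->  69.8 %
  p = 0.8 ->  91.8 %
```

Reading: half the animals show moderate-to-severe leakage when ~70% of the
injected VEGF escapes neutralization; risk starts rising once roughly 40%
of the challenge VEGF is free. The other examples cover affinity fitting
(`01`), IC50 comparison (`02`), size-scaled half-life prediction and NCA
(`03`), challenge simulation and the discriminating design window (`04`),
and the end-to-end pipeline (`06`). Each prints the numbers it computes and
one line on what they mean.

A thin CLI mirrors the stages:

```bash
ocuvegf simulate-study --seed 17 --out study/
ocuvegf fit-kinexa --input study/kinexa_aflibercept.csv
ocuvegf nca --input study/vitreous_pk.csv --dose-ug 1000 --agent aflibercept
ocuvegf fit-leakage --input study/leakage_scores.csv
ocuvegf run-all --seed 17 --out report/
```

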