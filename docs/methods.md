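# Methods

This note documents the models implemented in ocuvegf, their assumptions,
the defaults and why, and what the synthetic-data generators do and do not
emulate.

## Units and configuration

Canonical internal units are days, mL, nM, and µg; molar (M, pM, fM) is
used where assay convention demands (dissociation constants). All file I/O
converts at the boundary. Agents, eye geometry, and the challenge design
live in one YAML config with strict validation (unknown keys rejected by
name). Molecular weights (115/26/48 kDa; VEGF-A165 dimer 38.2 kDa protein
core) and rabbit eye geometry (vitreous 1.5 mL, aqueous chamber 0.3 mL,
aqueous outflow 3 µL/min, 0.9 cm effective diffusion path, vitreous
viscosity 0.7 mPa·s at 312 K) are literature-sourced defaults, marked as
such and overridable — they are inputs to the size-scaling model, not
measured quantities of this package. Binding stoichiometry defaults: the
receptor trap sequesters one VEGF dimer per molecule (1 site/drug, 1
drug-site/dimer); the Fab and scFv each occupy one epitope of the
homodimer (1 site/drug, 2 drug-sites/dimer). An explicit
`kd_temp_factor` hook converts assay-temperature (23 °C) K_D to body
temperature; the default is 1.0 (no correction) because no published
correction factor is available for these reagents — users with measured
van 't Hoff data can supply one.

## Solution-equilibrium affinity (KinExA)

The measured signal is proportional to the free inhibitor-site fraction at
equilibrium, which solves the 1:1 site mass balance exactly (quadratic; we
use the cancellation-safe conjugate form where I − L − K_D < 0, which
matters at femtomolar K_D). Equilibration time and bead-contact kinetics
are treated as satisfied assumptions, not modelled.

The N-curve fit estimates one shared K_D across all curves with per-curve
amplitude and background. Because the model is linear in the per-curve
parameters at fixed K_D, we profile K_D by variable projection: a fixed
15-start grid on log10 K_D ∈ [−16, −9] (mol/L) followed by bounded scalar
refinement, ties broken toward the smaller K_D. This makes the fit
deterministic, fast (~10 ms for six 10-point curves) and free of
initialization luck. An optional per-curve linear drift in injection order
multiplies the predicted signal by (1 + d·i/(n−1)); it is off by default
and our functional form is declared, not claimed identical to the vendor
software's unpublished correction. Identifiability guards: data that a
per-curve constant fits nearly as well (R²-type improvement < 0.5) or an
optimum pinned to the grid edge raise a fit error with diagnostics instead
of returning silent nonsense.

The 95% CI is a profile-likelihood interval: K_D is scanned with nuisance
parameters re-solved exactly, bounded where SSR crosses
SSR_min·(1 + F(1, n−p; 0.95)/(n−p)); a side that never crosses within the
search range is flagged open rather than given a fabricated bound.
Concentrations are interpreted as binding-site concentrations throughout;
valency conversion is the configuration layer's job.

## Cell potency (4PL)

Responses are pre-normalized peak responses (1 = uninhibited VEGF
response); raw fluorescence kinetics are out of scope. The 4PL is fitted by
least squares with deterministic initialization (IC50 start = concentration
nearest the half-range response) and the Hill slope bounded to [0.3, 5] to
prevent pathological fits. Non-descending data raise an error (no
inflection to estimate). Tukey comparisons use the studentized range on
replicate log-IC50s (classic HSD, Tukey–Kramer for unequal n) when groups
are replicated, falling back to delta-method standard errors for single
fits; with two groups the adjusted p reduces exactly to the two-sided
t-test, which is tested.

## Ocular pharmacokinetics

**Size-scaling prediction.** Biologics are assumed to leave the eye by the
anterior route only: diffusion through the vitreous (first-order transfer
rate k_vt ∝ D/L², with Stokes–Einstein D = kT/6πηr_h and compact-globule
r_h = 0.66·MW^(1/3) nm) followed by aqueous turnover clearance
(k_aq = outflow/aqueous volume ≈ 14.4/day). The terminal half-life is
ln2 over the slowest eigenvalue of the two-compartment linear system; with
rabbit geometry k_vt ≪ k_aq, so t½ ∝ r_h ∝ MW^(1/3). A single geometry
factor is calibrated against one reference agent's (MW, t½) anchor —
absolute Stokes–Einstein rates are exposed but not the default, because
they depend on an effective diffusion path that is itself a calibration.
No posterior elimination, melanin binding, or Fc recycling is modelled.
Each agent's hydrodynamic radius can be overridden (relevant for non-
globular fusion proteins, whose effective radius may exceed the
compact-globule value).

**NCA.** Phoenix-style conventions: λz from the adjusted-R²-maximizing
log-linear suffix of ≥ 3 post-peak points (peak excluded; ties within 1e-4
go to the longer window); linear-up/log-down trapezoidal AUC and AUMC with
c_last/λz tails; C0 back-extrapolated log-linearly from the first two
points (first observation reused if the profile does not decline there);
CL = dose/AUC_inf; V_ss = CL·AUMC/AUC. On noiseless monoexponential input
every quantity is exact against the closed form, which is tested to 1e-9.
Destructive-sampling profiles (repeated nominal days) are pooled by
geometric mean of quantifiable samples per day — unbiased for the
median-1 lognormal noise model — and the first day on which at least half
the samples fall below the LLOQ ends the profile (censored values are
never imputed; a majority-censored day cannot be pooled without bias).
Per-animal NCA is available by passing an unpooled profile.

## VEGF-challenge pharmacodynamics

Drug (D), VEGF (V), and complex (C) follow mass-action kinetics with
species-specific first-order elimination. Association is taken
diffusion-limited, k_on = 1e6 M⁻¹s⁻¹, with k_off = k_on·K_D; since binding
is then ~10⁴-fold faster than ocular elimination, the default integrator
is a quasi-equilibrium reduction — only the two running totals are
integrated, partitioned algebraically by the binding quadratic at each
step — with the full stiff three-species ODE (Radau, rtol 1e-8) retained
as the verification oracle; the two agree within 1% of free-VEGF AUC in
the regime that matters (tested). The quasi-equilibrium mode also removes
the sub-minute association transient, which the nominal output grid of the
full ODE cannot resolve and which contributes < 0.2% of the vehicle AUC.

Elimination half-lives of VEGF (38.2 kDa dimer) and of each drug–VEGF
complex (sites_per_vegf · MW_drug + MW_VEGF) come from the same MW^(1/3)
scaling, anchored per agent to that agent's own (MW, observed t½) pair —
each agent's measured half-life calibrates the size model without
cross-agent assumptions. Endogenous rabbit VEGF is ignored: the challenge
is exogenous human VEGF-A165, and two of the three agents have little or
no rabbit cross-reactivity.

The readout, percent free VEGF, is the trapezoid-integrated free-VEGF AUC
over injection → +47 h, normalized to a vehicle run through the same
integrator (so quadrature bias cancels). Protection timecourses decay the
drug monoexponentially from its day-0 vitreous concentration and map
percent free VEGF through the leakage logistic.

**Design-window search.** The discriminating window is the contiguous run
of days on which at least one agent pair is separated by more than a
probability margin (default 0.05), subject to every pair separating
somewhere in the run and every agent crossing p = 0.5 inside it. The
"any pair" day-wise rule reflects how the loss-of-protection sequence
unfolds: when the weakest agent is failing, the two stronger ones are
still indistinguishably protective, yet the day clearly discriminates.
Margin 0 gives the widest window; the window shrinks monotonically with
the margin; identical agents give an empty window.

## Leakage exposure–response

Scores are dichotomized at ≥ 2 (moderate-to-severe); the ordinal scale is
assumed 0–4 but only the cut matters. The stated vehicle week-10 exclusion
is the default rule, applied with a per-record log. The two-parameter
logistic is parameterized as (x50, slope) so back-calculated exposure
tables read directly; the GLM intercept/coefficient form is a property.
Fitting is Bernoulli ML via statsmodels Logit; complete separation is
flagged and reported from a weakly regularized fit at the identifiability
boundary rather than raised. Observations are treated as independent
Bernoulli trials even though animals contribute up to two challenges; a
cluster-robust (by animal) standard error for x50 is available but off by
default, matching the simple-logistic analysis the readout is designed
for. Reported accuracy is in-sample and labelled as such. The "risk
elbow" — the free-VEGF level where leakage risk starts to rise — is
reported as x at a configurable low probability (default p = 0.1) and is
interpretive, not a fitted parameter.

## Synthetic study generators

The generators define the study conditions:

- KinExA: duplicate curves at the published designs (aflibercept constant
  2.5/5.0/50 pM, titration 48.8 fM–1 nM; brolucizumab 25/50/400 pM,
  0.12 pM–4 nM; ranibizumab 50 and 400 pM, 1.46 pM–10 nM — the published
  range "50–400 pM" is read as two constant levels), ~3-fold series with
  exact endpoints, multiplicative Gaussian noise, 2% CV default.
- Vitreous PK: 7 animals terminated per day at days 5/26/33/40/54/56
  (day 56 = day-54 challenge + 2-day observation), monoexponential decay
  from dose/vitreous-volume, median-1 lognormal inter-animal noise at 15%
  CV, censoring at the assay LLOQs (6.25 / 20.0 / 3.0 ng/mL for
  aflibercept / brolucizumab / ranibizumab).
- Leakage: 3 agents + vehicle × 6 challenge days × 7 animals; animals are
  assigned (first, final) challenge-day pairs — (5,40), (26,54), (33,68) —
  so no animal receives more than two VEGF exposures; outcomes are
  Bernoulli draws from the logistic truth (default x50 = 70,
  slope = 24/ln4 ≈ 17.31) evaluated at the animal's actual observation lag
  (47 ± 3 h uniform jitter), while the recorded percent-free covariate is
  the nominal-lag value an analyst would assign; ordinal scores are
  synthesized as 0/1 (non-leaking) or 3 (leaking) since only the ≥ 2 cut
  is consumed. Under this pairing the default study uses 84 experimental
  animals (168 observations) plus satellite PK animals; a design in which
  every observation were a separate animal would need 168.

What the generators do **not** emulate: real KinExA signal drift and
detection chemistry, biexponential distribution phases and matrix effects
in vitreous bioanalysis, endogenous VEGF, response drift across repeated
VEGF exposures, clustering of outcomes within animal, and the real
(unpublished) score distribution. Passing recovery tests therefore show
the estimators are correct and well-calibrated under the declared noise
model at the study's sample sizes — not that real data would behave this
well.

## Pipeline

`run_pipeline(seed, out_dir)` chains generate → N-curve fits → 4PL/Tukey →
NCA → size-model prediction (anchored to the NCA-recovered ranibizumab
half-life, keeping the prediction self-contained in the generated study) →
leakage fit with exclusions → protection timecourses (using NCA-recovered
half-lives) → design window, and writes JSON/CSV/markdown reports plus a
diagnostic figure. Reports embed provenance (seed, config hash, version)
and are byte-identical under a fixed seed.

## Problem sizes and numerical choices

Recovery studies use 50 seeded replicates for affinity and potency and 100
for NCA half-life — enough for a stable median while the full suite runs
in well under a minute per module. ODE tolerances are rtol 1e-8 /
atol 1e-12; free-VEGF AUCs use a uniform 481-point grid (2001 when
benchmarking against the stiff oracle). The K_D grid spans [1e-16, 1e-9] M,
bracketing all plausible anti-VEGF affinities. Degenerate inputs (flat
binding curves, non-inhibiting potency data, profiles without terminal
decline, single-class leakage outcomes) raise typed errors carrying
diagnostics.

## Known limitations

- The anterior-route size scaling ignores posterior elimination and
  protein-shape effects; the aflibercept trap's effective radius may
  exceed the compact-globule value (override available).
- Percent free VEGF enters the logistic as a model-assigned covariate;
  errors in the PK/PD chain propagate into (x50, slope) as attenuation,
  exactly as in the original analysis design.
- In-sample accuracy overstates out-of-sample performance; no
  cross-validation is built in.
- The quasi-equilibrium reduction is invalid if k_on is set orders of
  magnitude below the diffusion limit; use the full ODE mode there.
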