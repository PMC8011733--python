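# Methods

## The model

`ogtt-persona` simulates plasma glucose and insulin after a 75 g oral glucose
load with a two-compartment ordinary-differential-equation model of the
insulin-mediated glucose regulatory system. Four states are tracked: glucose
mass in the gut `M` (mmol), plasma glucose `G` (mmol/L), plasma insulin `I`
(mU/L), and the accumulated glucose elevation `J = ∫(G − G_b) dt` that feeds
the integral branch of insulin secretion.

Gastric emptying delivers the bioavailable dose `f·D` into the gut with a
Weibull-shaped rate

    Ra(t) = f·D · σ k₁ (k₁t)^(σ−1) exp(−(k₁t)^σ),

which reduces to exponential decay at shape factor σ = 1 and integrates to
`f·D` over [0, ∞). Glucose transfers from gut to plasma at first order (k₂).
The plasma balance combines

* net hepatic glucose flux `EGP_b − k₃(G − G_b) − k₄β(I − I_b)` — basal
  endogenous production suppressed by glucose and insulin elevation. The term
  is deliberately not clamped at zero: during postprandial hyperinsulinemia
  the liver switches to net glucose uptake, so a negative net hepatic flux is
  physiological;
* insulin-independent uptake by obligate glucose oxidizers (brain, red blood
  cells), Michaelis–Menten in glucose and normalized so that it equals its
  basal flux at `G_b`;
* insulin-dependent peripheral uptake `k₅ β I · G/(K_M + G)`;
* renal excretion `c₁(G − G_th)/V_G` above the renal threshold.

Insulin secretion is a proportional–integral–derivative (PID) response to
glucose elevation, `[k₆(G − G_b) + (k₇/τ_i)·J + k₈τ_d·dG/dt]/β`, clamped at
zero because the pancreas cannot secrete at a negative rate; the clamp binds
only when glucose falls below basal. The derivative branch uses the
algebraically computed `dG/dt` from the same right-hand-side evaluation — no
numerical differentiation of a noisy signal. The integral state `J` is not
clamped and may go negative during below-basal excursions. Insulin is cleared
by the liver (fixed rate `c_liv`) and by transfer/degradation in the
interstitial fluid (`k₉`); both clearance terms are linear in the elevation
`I − I_b`, so the fasting state carries no net insulin flux and basal insulin
turnover is absorbed into the steady state.

`EGP_b` is not a stored constant: it is computed as the balance term that
makes `(M, G, I, J) = (0, G_b, I_b, 0)` an exact equilibrium. Every
simulation starts there, so fasting model values equal the measured fasting
values exactly.

### Units and conversions

Glucose mmol/L, insulin mU/L, time minutes, dose grams; grams of glucose
convert to mmol with 1000/180.16. The Matsuda index internally converts
glucose to mg/dL (× 18.016).

### Reference parameterization

The packaged constants file (`src/ogtt_persona/data/reference_constants.json`)
holds the population constants and an average-healthy reference vector
k₁…k₉, chosen once so that the reference simulation shows textbook NGT
morphology: glucose peaks near 7.7 mmol/L around 40 min and returns to
~5.8 mmol/L by 120 min; insulin peaks near 50 mU/L and approaches basal by
late times. The shape factor σ = 1.34 (Weibull emptying rather than the pure
exponential fallback) and K_M = 5 mmol/L are fixed, never estimated.
Population constants: V_G = 0.17 L/kg, body weight 70 kg (configurable — the
model volumes do not use per-individual anthropometrics), bioavailability
f = 0.9, renal threshold 11 mmol/L, τ_i = 100 min, τ_d = 10 min, β = 1,
c_liv = 0.03 min⁻¹, basal insulin-independent uptake 0.55 mmol/min.

## Parameter estimation

One individual's data are the five-point glucose and insulin curves at
t = 0, 30, 60, 90, 120 min. The objective is the combined weighted sum of
squared residuals

    SSR = Σ_j Σ_i ( γ_j (y_ij − d_ij) )²,   γ_glucose = 1, γ_insulin = 0.1,

where the insulin weight compensates the mmol/L vs mU/L scale difference.
Minimization uses bounded trust-region-reflective nonlinear least squares on
the weighted residual vector (glucose block then insulin block), with bounds
[10⁻⁴×, 10³×] the reference value of each free parameter and the reference
values as the scaling vector. To escape local minima the solver restarts from
multiple initializations: start 0 is the unperturbed reference, every further
start multiplies each free parameter independently by a uniform draw from
[0.75, 1.25] (25% start noise). Fifty starts are the estimation default; the
selection pipeline and the large synthetic experiments use ten, which on this
model reaches the same optima in bench comparisons. Non-estimated parameters
stay at reference values; each individual's `G_b`/`I_b` are set to their
measured fasting values. Solver tolerances are 1e-10 (function and step); a
start counts as converged when the solver reports success, and the returned
fit is the lowest-SSR converged start. Everything is deterministic given the
configured seed.

## Parameter-subset selection

Stage (i) — local sensitivity. Each rate constant is perturbed by ±75% with
the others held at reference, and the deviation of the perturbed glucose and
insulin curves is scored as `‖pert − ref‖₂ / ‖ref − basal‖₂` on a 1-minute
grid over [0, 240] min. A parameter is sensitive when its largest deviation
across directions and outputs exceeds a configurable cutoff (default 0.30,
calibrated once on the reference parameterization and recorded in every
report; perturbation size and cutoff are independent knobs). At the default
the sensitive set is {k₁, k₄, k₅, k₆, k₈, k₉}: gut–plasma transfer (k₂) is
not rate-limiting, glucose-driven EGP suppression (k₃) and the integral
secretion gain (k₇) are small at reference. A perturbed simulation failure
marks the parameter unstable and therefore sensitive.

Stage (ii) — candidate evaluation. All subsets of the sensitive parameters
with 3–6 members (42 candidates for 6 sensitive parameters) are fitted on
seven representative responses: the per-time-point median curves of the five
ADA phenotype groups (NGT, IFG, IGT, IFG&IGT, T2DM; even-count medians are
the mean of the central pair) plus the individuals with the smallest and
largest glucose AUC. Candidates are ranked by the summed per-curve
least-squares AIC, `Σ_c [10·ln(SSR_c/10) + 2p]`: the parsimony penalty is 2p
per curve because each candidate re-estimates its p parameters independently
on every representative response. Ties break toward the smaller subset, then
lexicographic names.

Stage (iii) — identifiability gate. Candidates are profiled in ascending AIC
order. For each parameter of a candidate, the profile fixes it on a
log-spaced multiplicative grid around its optimum ([0.1×, 10×], warm-started
refits of the remaining parameters, early stop two points after the df = p
threshold) and converts SSR ratios to the likelihood-ratio scale
`n·ln(SSR_PL/SSR_opt)` under a Gaussian constant-variance error model.
Thresholds are the 0.95 quantiles of χ² at df = 1 and df = p. A parameter is
identifiable when the df = 1 threshold is crossed on both sides, structurally
non-identifiable when the whole profile is flat within 1% of the anchor SSR,
practically non-identifiable otherwise; confidence intervals collect the grid
points under the df = 1 threshold. Identifiability is a selection criterion,
not a post-hoc check: the selected model is the best-ranked candidate whose
parameters are identifiable on all but at most one of the seven curves
(isolated non-identifiability on an extreme response is tolerated). This gate
is what rejects parameter supersets: the median curve of a heterogeneous
group is systematically broader than any single model trajectory, and a freed
insulin-kinetics parameter (k₉) will absorb that structure while profiling
flags it as non-identifiable.

On synthetic benchmark cohorts with heterogeneity confined to
{k₁, k₅, k₆, k₈} the pipeline selects exactly that subset at most seeds; the
margin is intrinsically slim (the fit improvement of a superset sits close to
the AIC penalty), so the packaged self-consistency check runs as a fixed-seed
regression.

## Synthetic cohorts

The generator emulates the structure of a large baseline OGTT cohort of
overweight/obese adults: five ADA phenotype strata with mixing weights
roughly 67/6/6/16/5% (NGT largest), log-normal rate-constant variation,
truncated-normal fasting values (fasting glucose capped below the renal
threshold), a 75 g dose sampled at the canonical five time points, and
independent multiplicative log-normal measurement noise with CV 2% for
glucose and 10% for insulin (log-scale σ chosen so the empirical CV matches
exactly; zero CV is the identity). Insulin-dependent uptake (k₅) and the
secretion gains (k₆, k₈) decrease from NGT to T2DM, so fitted parameters
correlate with the Matsuda and insulinogenic indices as expected. Default
CVs are 25–35% for the four discriminating constants and 10% elsewhere. The
measured fasting values are the noisy versions of the generating basal
values, exactly as the estimation module consumes real data. A second prior
set (`selection_benchmark_priors`) confines parameter variation to
{k₁, k₅, k₆, k₈} (30% CV, more balanced stratum weights so small cohorts
populate every ADA group) for recovery and self-consistency experiments.

What the generator does not emulate: anthropometrics (age, sex, BMI),
day-to-day intra-individual variability, assay-specific error structure
(e.g. heteroscedastic immunoassay noise), and real-world model misfit —
synthetic curves come from the same model family that is fitted, so recovery
tests demonstrate estimator correctness and identifiability, not structural
adequacy for real OGTT data. Synthetic insulin excursions span roughly
2–100 mU/L, narrower than the extremes of real cohorts.

## Numerical choices

The integrator is an adaptive embedded Dormand–Prince RK5(4) pair compiled
with numba (defaults rtol 1e-8, atol 1e-10, max step 5 min; requested output
times filled by cubic Hermite interpolation inside accepted steps). The
system is non-stiff at physiological scales; halving the tolerances changes
outputs by far less than 0.1%, and the kernel agrees with an independent
scipy `solve_ivp` route to ~1e-8 relative. Fitting paths use rtol 1e-6 for
speed. The typed flux functions in `model.py` are the reference algebra; the
test-suite asserts exact agreement between them and the jitted kernel.
Experiment sizes in the packaged checks (cohorts of 20–200, ten multi-starts,
8-point profile grids per side) were chosen to make the full suite a
desk-scale run while leaving every conclusion unchanged at larger settings.

## Known limitations

* k₄ (insulin-driven EGP suppression) and k₅ (insulin-dependent uptake) act
  through the same plasma-insulin signal and are nearly interchangeable on
  five-point data; profiling exposes this as mutual non-identifiability when
  both are freed.
* The secretion clamp prevents plasma insulin from dropping below basal;
  real post-challenge insulin can mildly undershoot.
* ADA thresholds are hard-coded to the standard two-hour OGTT criteria
  (fasting 5.6/7.0, 2-h 7.8/11.1 mmol/L) with boundary values assigned to
  the impaired class; the insulinogenic index uses the 0→30 min increment
  form and the Matsuda index the five-point composite form.
* Group comparisons simulate the fitted group-median model against each
  member's data; groups left empty by classification are omitted with a
  warning rather than an error.
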