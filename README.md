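# ogtt-persona

Personalized mechanistic models of the glucose–insulin system from standard
five-point oral glucose tolerance test (OGTT) curves.

Fasting and 2-hour glucose — the values clinical diagnosis relies on — ignore
the dynamics of the post-load response and the interplay between glucose and
insulin. This package fits a physiology-based two-compartment ODE model to
each individual's measured glucose *and* insulin trajectory (t = 0, 30, 60,
90, 120 min after a 75 g load), turning every response into a small set of
interpretable rate constants: gastric emptying (k₁), insulin-dependent
glucose uptake (k₅), and glucose-driven insulin secretion — proportional
(k₆) and rate-of-change dependent (k₈). It is written for researchers in
metabolic phenotyping and personalized nutrition who have cohort OGTT data
and want per-individual mechanistic parameters rather than single-time-point
indices.

## The model and the pipeline

States: gut glucose mass `M`, plasma glucose `G`, plasma insulin `I`, and
the integral of glucose elevation `J`. Gastric emptying is Weibull-shaped
(`∫Ra dt = f·D`), gut→plasma transfer is first order, the net hepatic flux is
`EGP_b − k₃(G−G_b) − k₄β(I−I_b)`, peripheral uptake is
`k₅βI·G/(K_M+G)` plus a basal-normalized insulin-independent term, and
secretion is a PID controller `[k₆(G−G_b) + (k₇/τ_i)J + k₈τ_d dG/dt]/β`.
Fitting minimizes the combined weighted sum of squared residuals

    SSR = Σ_j Σ_i (γ_j (y_ij − d_ij))²,  γ = 1 (glucose), 0.1 (insulin)

with multi-start bounded nonlinear least squares (50 starts, 25% start
noise).

Because nine rate constants cannot all be estimated from ten data points,
a systematic selection pipeline decides which parameters to personalize:

1. **Local sensitivity analysis** — ±75% one-at-a-time perturbation; only
   parameters that visibly reshape the response stay in play.
2. **AIC-scored subset search** — every subset of 3–6 sensitive parameters
   is fitted on seven representative curves (the five ADA phenotype-group
   medians plus the extreme responses by glucose AUC) and ranked by summed
   per-curve AIC.
3. **Profile-likelihood identifiability** — candidates are accepted in AIC
   order only if every parameter's likelihood profile crosses its χ²
   confidence threshold (df = 1 and df = p) on essentially all curves.

On cohorts generated with heterogeneity in {k₁, k₅, k₆, k₈} the pipeline
recovers exactly that subset, and the personalized fits cut the
data–simulation discrepancy many-fold relative to phenotype-group median
models. A synthetic-cohort module generates realistic virtual
populations (five ADA strata, log-normal parameter variation, multiplicative
assay noise) with known ground truth, so every stage is testable without any
clinical data. See `docs/methods.md` for the full model description and
numerical choices.

## Worked example

Simulate the average-healthy reference response:

```bash
$ ogtt-persona simulate --dose 75
time_min,glucose_mmol_l,insulin_mu_l
0,5.0000,8.0000
30,7.2820,42.3498
60,7.1933,25.2517
90,6.4509,14.6220
120,5.8054,10.2673
```

Glucose rises from the fasting 5.0 mmol/L to a peak near 30–45 min and is
back below 6 mmol/L by two hours; insulin peaks around 42 mU/L and returns
toward basal — normal glucose tolerance morphology.

Generate a small virtual cohort and personalize it:

```python
import ogtt_persona as op

p, c = op.reference_parameters(), op.reference_constants()
cohort = op.generate_cohort(5, op.default_priors(p), c, seed=42, reference=p)
cfg = op.FitConfig(("k1", "k5", "k6", "k8"), n_starts=10, seed=0)
pers = op.personalize_cohort(cohort.responses(), cfg, c, reference=p)
print(pers.parameter_table().round(4).to_string(index=False))
```

```
individual_id label    ssr  matsuda  insulinogenic     k1     k5     k6     k8
        S0000   IGT 0.0728   3.6975        10.1274 0.0190 0.0012 0.4956 2.6422
        S0001  T2DM 0.0313   3.8432         8.1989 0.0220 0.0040 0.3849 2.3194
        S0002   NGT 0.0668   9.3931        11.5820 0.0253 0.0121 1.1424 1.9240
        S0003   NGT 0.0871   7.1714        12.7705 0.0206 0.0084 0.7387 3.3536
        S0004   NGT 0.0759   9.5885         8.2122 0.0273 0.0130 0.5909 2.1169
```

Each row is one virtual participant: ADA label from fasting/2-h glucose, the
weighted SSR of the personalized fit, the Matsuda and insulinogenic surrogate
indices computed from the raw curves, and the four fitted rate constants.
The impaired individuals (IGT, T2DM) show markedly lower insulin-dependent
uptake k₅ and secretion gain k₆ than the NGT participants — the mechanistic
signature the model extracts — and their lower Matsuda index agrees.

The same steps are available from the shell: `ogtt-persona synth`, `fit`,
`select`, `personalize`, and `analyze` (PCA biplot and per-group parameter
boxplots); data are tidy CSVs with columns
`individual_id,time_min,glucose_mmol_l,insulin_mu_l`.

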