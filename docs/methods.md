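# Methods

This note records the models, conventions and design choices behind the
package, in the order the pipeline applies them.

## Synthetic cohorts

**Concentration model.** Every quantified variable (41 metabolites, 112
lipoprotein parameters, 3 spectral inflammation bins) is log-normal.
On the log scale a control sample is

    log x_v = mu_v + covariate terms + sigma_bio * z_v(subject) + sigma_meas * eps_v(sample)

with `sigma_bio = sqrt(log(1 + biological_cv^2))` (between-subject, default
CV 0.25) and `sigma_meas` likewise from the analytical CV (default 0.10).
Typical levels `mu_v` are fixed per variable from a stable name hash
(metabolites 0.05–5 mmol/L, lipoprotein parameters 5–150 mg/dL, spectral
bins 10⁻³–10⁻²). Between-subject scores are equicorrelated within
lipoprotein blocks — one block per subclass (V1…H4, five analytes each)
and per main fraction (eight parameters each), within-block r = 0.5 — and
independent elsewhere; the three inflammation bins form their own r = 0.5
block. Mild age and sex covariate effects (age slope on lipoproteins,
sex shifts on creatinine and two lipoprotein parameters) give the
screen's covariate adjustment something real to adjust for.

**Planted effects.** Acute-group shifts are applied on the log scale in
units of the control group's *marginal* SD (biological + analytical +
covariate variance), which makes the downstream effect estimator
(group coefficient ÷ control log-SD) unbiased by construction. The
default healthy-vs-acute panel has 38 members with |effects| spaced over
0.7–2.0 SD and signs matching the acute serum signature (amino acids
both ways, glycoprotein signals and VLDL triglycerides up, HDL
cholesterol and ApoA-I down). The lower edge is a power choice: at
400 samples per group the effect-estimate SE is ≈0.075 SD, so a 0.7-SD
minimum keeps each member's chance of missing the 0.5-SD selection floor
below 0.5%. The acute-vs-acute panel (14 triglyceride-centred members)
spans 0.9–2.0 SD for the same reason at its smaller n = 115 design
(SE ≈ 0.14 SD). Same-block panel pairs are kept weak enough that their
*pooled* correlation — which includes the between-group mixture
component — stays well below the 0.8 pruning threshold.

**Recovery trajectories.** Each longitudinal subject draws a true
recovery day `T` from a generalized extreme value law; the defaults are
the study-scale parameters (location 62.44 d, scale 30.16 d, shape 0.34,
evd convention). `T` is then multiplied by a severity factor
(mild-moderate 1.0 with probability 0.6, severe 1.35 — matching the
ratio of the published severity sub-models) and shifted by
0.5 days per year of age around the cohort mean; both modulations can be
switched off, in which case the marginal law is exactly the configured
GEV (this is the configuration under which the distributional
goodness-of-fit tests run). Panel displacement decays *linearly* from the
full acute effect at day 0 to zero at day `T` and stays at zero after —
linear because the recovery-day estimator is a linear model; the
population-level near-exponential appearance emerges from mixing linear
subjects with GEV-distributed `T`. Sampling days are drawn uniformly
within the follow-up bins (0,7], (7,14], (14,30], (30,60] and (60,120]
(the ">60 days" bin capped at 120), each bin visited with a probability
tuned to the sparse design of the study cohorts (≈3 follow-ups per
subject in expectation).

**Noiseless mode.** Planted effects are defined in SD units, so a table
with all noise off would have zero displacement; with both CVs zero the
effect unit therefore falls back to a fixed reference log-SD (that of the
default CVs). Noiseless trajectories are then exactly linear, which is
what the estimator-exactness tests exercise. Those tests use the fitted
model's score of the true control-mean vector as the healthy reference:
the only residual error otherwise is the sampling error of the training
cohort's scaling statistics, which is a property of the training draw,
not of the estimator under test.

**Cytokines.** Thirteen markers with log-normal baselines (CV 0.40).
Configured markers are elevated in acute samples (defaults IL-1RA ×3,
IP-10 ×4, IL-6 ×2.5, MCP-1 ×2) and decay linearly from day 8 back to the
healthy mean over a per-subject duration; the MCP-1 duration is coupled
to the subject's metabolic recovery day at a configurable correlation
(default 0.8).

**What the generator does not emulate.** No spectral artifacts, batch or
hospital effects, missing metadata, non-linear or relapsing trajectories,
informative dropout, or vaccination immunology. Passing tests therefore
certify the *estimators* under the stated statistical structure, not
robustness to every failure mode of real cohorts.

## Preprocessing conventions

* Day labeling: a hospitalized subject's earliest sample is day 0 (and
  flagged acute) when collected within 7 days of admission; later samples
  count from it. Without a qualifying first sample, days count from the
  hospitalization date and no sample is acute. Non-hospitalized recovered
  subjects count from their reported infection date. Days are whole-day
  date differences.
* Spectral buckets are half-open `[0.5 + 0.03k, 0.5 + 0.03(k+1))`
  (300 buckets); points in [4.7, 5.0) contribute neither to buckets nor
  to the normalizing total, so bucket values sum to 1. The named bins do
  not fall on bucket centers of a 0.5-anchored grid; "centered at x" is
  resolved to the nearest bucket center with exact ties going to the
  lower-ppm bucket (logged). On this grid GlycA and GlycB are adjacent.
* QC clustering standardizes the raw variables (population SD) and runs
  DBSCAN with eps = 20, minPts = 5 on Euclidean distance; any cluster
  member is kept, noise points are discarded. Constant variables are
  dropped from clustering with a warning.
* Log-standardization uses the natural log (the base is absorbed by the
  unit-variance scaling); zeros are replaced by half the variable's
  smallest positive value; variables constant on the training set are
  dropped with a warning. Training statistics are carried inside the
  model and reapplied verbatim in projection mode.

## Screening

One least-squares fit per variable of log-value on group + age + sex
(sex as a single male indicator). Because every variable shares the same
regressor matrix the fits are solved in one vectorized pass; a
statsmodels OLS cross-check is part of the test suite. The effect size is
the group coefficient divided by the control group's log-scale SD
(log-scale chosen for coherence with the modeling matrix). BH adjustment
runs across all tested variables; selection requires adjusted p < 0.05
and |effect| ≥ 0.5 SD. Pruning is greedy by descending |effect| with
alphabetical tie-break, dropping any candidate with pooled
(cases + controls) Pearson |r| > 0.8 against an already-kept variable —
pooled because pruning serves the parsimony of the modeling matrix; the
greedy order realizes "keep the largest absolute effect" on arbitrary
correlation graphs.

## Discrimination model

Single-response orthogonal filtering with exactly one predictive and one
orthogonal component (the component count is fixed, not selected). With
`y` centered: `w ∝ X'y`; the orthogonal weight is the component of the
loading `p = X't/t't` orthogonal to `w`; the orthogonal scores are removed
from `X` and the predictive component is recomputed on the filtered
matrix. This construction guarantees `‖w_pred‖ = ‖w_orth‖ = 1`,
`w_pred ⊥ w_orth` and `t_pred ⊥ t_orth` exactly, and reduces to
single-component PLS1 when the filtering step is disabled (asserted
against scikit-learn's PLS). The model is oriented so the case class has
positive mean t_pred. Cross-validation is stratified 5-fold repeated 10
times with scaling and fitting inside each training split; the per-sample
out-of-fold t_pred averaged over repeats feeds the ROC analysis, while
the full-data refit is the reporting/projection model. If a training
split contains no orthogonal structure at all, a fixed unit direction
orthogonal to `w` stands in so the component dimensions stay stable (its
scores are then ≈0 and the filtering is a no-op).

## Evaluation

AUC by the rank (Mann–Whitney) formulation with half-credit for ties;
curve thresholds at midpoints between consecutive observed scores. The
Youden cutoff maximizes sensitivity + specificity − 1; ties — which
always arise under complete separation — resolve to the threshold
nearest the midpoint of the two class means. Permutation tests rerun the
entire cross-validation per label permutation (default 100 runs) and use
the add-one p-value `(1 + #{permuted ≥ observed})/(runs + 1)`, which never
returns zero.

## Recovery analysis

`D = t_pred − t̄_pred(HC)`: the offset constant is fixed so the distance
vanishes exactly at the healthy-control mean score. A sample counts as
*recovered* when its score is on the healthy side of the Youden cutoff —
the only decision boundary the model constructs. Note the two
conventions meet at different points: under the linear trajectory model a
subject crosses the cutoff at roughly half its true recovery day, so
cutoff-based recovered fractions lead the true-recovery fractions
substantially (the (30,60] bin fraction sits near 0.6 under the default
generator, whereas the fraction of subjects with true recovery day ≤ 60
is F_GEV(60) ≈ 0.34).

Per-subject recovery days come from OLS of t_pred on day over all of the
subject's samples (eligibility: an acute day-0 sample plus a follow-up at
≥14 days; a stricter three-sample mode is a config switch). Samples
collected after the subject has plateaued flatten the fitted slope, so
estimated recovery days are biased long relative to the generator's
truth — an estimator property shared with any linear fit through a
saturating trajectory. Non-recovering fits (slope ≥ 0 or a crossing in
the past) are excluded from the distribution fit and counted in the
report.

The GEV is fitted by maximum likelihood (scipy's genextreme) initialized
from probability-weighted moments, with the support constraint verified
for every observation and an honest convergence flag. The package
reports both the density mode ("most probable recovery day") and the
model and empirical 95% quantiles, since summaries of a heavy-tailed fit
differ substantially between conventions. Sub-models are independent GEV
fits per severity class and per age group (split at 65 y); groups with
fewer than 10 valid estimates are skipped with a warning.

## Inflammation

Group comparison per marker: binary-log fold change of group means and a
two-sided Mann–Whitney test — exact by full enumeration when both groups
have ≤10 observations (correct under ties), scipy's exact method for
tie-free groups up to 20, tie-corrected normal approximation otherwise;
raw p at 0.05 with no correction across the 13 markers. Marker decay is
a least-squares line on a subject's samples from day 8 onward;
*half-recovery* is the day the line crosses the midpoint between the
acute and healthy means (the natural reading of "half"). The
MCP-1/metabolic coupling is the per-subject Pearson correlation of
half-recovery day against metabolic recovery day (slope available as an
alternative). Under the default sparse sampling and 40% cytokine CV the
per-subject decay estimates are noisy, so the estimated correlation
attenuates markedly relative to the generative coupling of 0.8 — visible
in the end-to-end pipeline report and expected of the matching real-data
analysis.

## Pipeline

Stages communicate through CSV/JSON files in the output directory so each
is independently runnable and resumable; every artifact carries a
provenance block (schema version, seed, hash of the analysis-relevant
configuration). Reports are byte-reproducible for a fixed seed. The
default problem sizes (400 + 400 cross-sectional, 400 longitudinal
subjects, 200 GEV replicates of n = 351, 20 screening seeds, 100
permutation runs) were chosen so a full analysis completes in minutes on
one CPU while keeping every Monte-Carlo check's sampling error an order
of magnitude below its tolerance.

## Known limitations

* The recovery-day estimator's plateau bias (above) inflates the fitted
  GEV location relative to the generator's truth; the parameter-recovery
  checks therefore sample the law directly.
* Recovered-fraction time courses depend strongly on the recovered
  convention (cutoff vs HC-mean crossing); both conventions are exposed,
  only the cutoff one is used in reports.
* The exact Mann–Whitney path is combinatorial and restricted to ≤10
  observations per group.
* No mixed-effects or censoring-aware models: subjects are fitted
  independently and non-recovering trajectories are excluded, not
  modeled.
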