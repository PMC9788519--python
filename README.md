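# phenorevert

Serum-metabolome disease discrimination and metabolic **phenoreversion**
analysis: how long does it take a patient's blood metabolome, knocked off
balance by severe COVID-19, to return to the healthy-population
distribution?

The package is aimed at metabolomics researchers working with quantified
¹H-NMR serum profiles (metabolite concentrations, lipoprotein subclass
parameters, and the GlycA/GlycB/SPC spectral inflammation signals). It
implements the full analysis chain:

1. **Preprocessing** — days-since-onset labeling from collection and
   hospitalization dates; fixed 0.03-ppm spectral bucketing over 0.5–9.5 ppm
   (residual-water region 4.7–5.0 excluded) with GlycA (2.06 ppm),
   GlycB (2.09) and SPC (3.23) bin extraction; DBSCAN sample QC
   (minPts = 5, eps = 20 in standardized Euclidean space); log-transform +
   autoscaling.
2. **Panel screening** — per-variable linear models of the log-value on
   disease group adjusted for age and sex; Benjamini–Hochberg FDR < 0.05;
   an absolute effect floor of 0.5 control-group SD; greedy correlation
   pruning at Pearson |r| > 0.8 keeping the largest absolute effect.
3. **Discrimination** — O-PLS-DA with one predictive and one orthogonal
   component (Trygg–Wold orthogonal filtering for a single binary
   response): scores t_pred / t_orth, 5-fold cross-validation repeated 10
   times, ROC/AUC on the out-of-fold t_pred, the Youden-optimal cutoff,
   and permutation tests (100 runs) for AUC / sensitivity / specificity.
4. **Recovery** — projection of longitudinal samples onto the model; the
   distance statistic D = t_pred − t̄_pred(HC); per-subject ordinary
   least squares of t_pred on days since onset, with the **recovery day**
   the day the line reaches the healthy-control mean score; a
   maximum-likelihood generalized extreme value (GEV) fit of the
   recovery-day distribution (evd sign convention: positive shape = heavy
   right tail); recovered-fraction time courses and severity / age≥65
   sub-models.
5. **Inflammation** — 13-marker cytokine panel group comparison (binary-log
   fold change + Mann–Whitney), per-subject linear marker decay from day 8,
   and the correlation between inflammatory (MCP-1) and metabolic recovery
   times.

Because the clinical serum data behind such studies are private, the
package ships a first-class **synthetic cohort generator**
(`phenorevert.synthgen`) producing log-normal concentrations with
correlated lipoprotein blocks, a planted acute effect panel in
control-SD units, GEV-distributed per-subject recovery times with linear
phenoreversion trajectories, sparse follow-up sampling, and a coupled
cytokine panel — all with recorded ground truth, so every estimator is
testable end to end.

## Worked example

Select the discriminating panel on a synthetic cohort
(`examples/screen_panel.py`):

```
$ python examples/screen_panel.py
selected 38 of 156 variables (planted panel: 38; exact match: True)

strongest depressions and elevations (effect in control-SD units):
variable  effect_sd         p_adj
    H1CH  -2.034005 2.584523e-130
    HDCH  -1.577638  1.138234e-90
    H2CH  -1.569976  3.379635e-82
     variable  effect_sd         p_adj
Phenylalanine   1.913432 6.457819e-114
         V1TG   2.002385 1.716174e-121
        GlycA   2.017709 8.332884e-119
```

The screen recovers exactly the 38 planted variables: HDL cholesterol
parameters depressed, phenylalanine, large-VLDL triglycerides and the
GlycA inflammation signal elevated — the acute-phase serum signature.

Fit the recovery-day distribution (`examples/fit_recovery_distribution.py`):

```
$ python examples/fit_recovery_distribution.py
n = 351, converged = True
location  66.50 d   (generating value 62.44)
scale     34.81 d   (generating value 30.16)
shape     0.352     (generating value 0.34)
most probable recovery day (mode): 56.5 d
model 95% quantile: 249 d; empirical 95% quantile: 248 d
```

A single sample of 351 subjects recovers the generating GEV parameters to
within sampling error; the positive shape produces the long right tail —
most subjects renormalize around two months, a minority takes far longer.

Other examples: `simulate_cohort.py` (planted vs observed effects),
`discriminate_and_project.py` (O-PLS-DA training, cross-validated AUC and
projection of follow-up samples), `run_full_pipeline.py` (everything end
to end through the file-based pipeline).

## Command line

The pipeline stages are also exposed as a thin CLI:

```bash
phenorevert run --out results/ --seed 0            # full chain
phenorevert simulate --out results/ --seed 0       # single stages
phenorevert bin --spectrum spec.csv --out results/
```

Stage configuration (cohort sizes, QC/selection/recovery thresholds,
permutation runs) comes from a YAML file via `--config`. Each stage reads
its inputs from and writes its outputs to the `--out` directory, so stages
are resumable and independently inspectable; every artifact carries a
provenance header (schema version, seed, config hash).

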