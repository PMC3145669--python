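# saeindex

Biologic phenotyping of the smoking response in the small airway
epithelium (SAE), the earliest site of smoking-induced airway disease.
Only a minority of smokers develop COPD, and bulk case/control
comparisons hide the fact that individual smokers respond to cigarette
smoke very differently at the transcriptome level.  `saeindex`
implements a complete, tested pipeline for quantifying that individual
response from probe-set-level expression matrices, for researchers
working with airway-epithelium (or similar case/control) microarray
cohorts:

1. **Smoking signature.** Genes responsive to smoking are selected from
   healthy smokers vs nonsmokers with the classic three-criterion
   microarray filter: Present detection call in ≥ 20% of samples, fold
   change of group means ≥ 1.5, and a t-test on log2 values with
   Benjamini–Hochberg adjusted p < 0.01.  Probes are collapsed to known
   genes (lowest-p probe per gene).
2. **The I_SAE index.** For each signature gene, the nonsmoker reference
   defines a normal range: within 2 SD of the log2 mean *in the
   direction of the smoking-induced change*.  For subject *i* with
   abnormality indicators E_g ∈ {0, 1},

       I_SAE(i) = c · Σ_g E_g ,   c = 100 / N ,

   the percent of the N index genes the subject expresses outside the
   nonsmoker range.  Healthy smokers at or below the median I_SAE are
   "low" responders; those above are "high" responders.
3. **Subgroup contrasts.** Genome-wide contrasts (same filter chain) of
   high vs low responders, COPD vs each responder subgroup, and the
   combined high+COPD vs low biomarker signature.
4. **Validation machinery.** Hierarchical-cluster validation on held-out
   samples, principal-component separation, cross-validated
   nearest-shrunken-centroid ("PAM") and max-margin classifiers, K-fold
   robustness of the normal ranges, and a covariate confounder screen.
5. **Synthetic cohorts.** A generator that plants smoking-responsive
   genes, a latent per-smoker responsiveness with bimodal low/high
   structure, inflated smoker variance and a COPD-like group drawn from
   the high-responder regime — with full ground truth, so every stage of
   the pipeline is testable against planted truth.

## Worked example

Run the whole pipeline on a simulated cohort matching the study design
(47 nonsmokers, 58 healthy smokers, 22 COPD smokers):

```python
import saeindex as sx

cfg = sx.RunConfig(
    simulate=sx.SimulationConfig(n_genes=400, n_responsive=50, seed=3),
    seed=3, output_dir="demo_run", kfold_repetitions=20,
)
results = sx.run_pipeline(cfg)
print(open(results["report_path"]).read())
```

prints (abridged):

```
- signature: 39 probe sets, 39 index-eligible genes (present >= 20%, FC >= 1.5, q < 0.01)

## I_SAE by group (percent of index genes out of range)

- nonsmoker: n=47, median 2.6%, range 0.0-10.3%, variance 8.5
- healthy_smoker: n=58, median 53.8%, range 2.6-94.9%, variance 945.6
- copd: n=22, median 84.6%, range 64.1-97.4%, variance 66.1

Responder split (median, boundary 53.84615384615384): 29 low / 29 high.
COPD smokers with I_SAE at/above the high-responder minimum: 100.0%.

## Genome-wide contrasts

- high_vs_low: 42 significant probe sets (...)
- copd_vs_low: 45 significant probe sets (...)
- copd_vs_high: 0 significant probe sets (...)
- highcopd_vs_low: 45 significant probe sets (...)
```

Reading the output: the signature recovered 39 of the 50 planted
smoking-responsive genes; nonsmokers express ~2–3% of index genes outside
their own reference range (the one-sided 2-SD tail), smokers far more and
bimodally; and the headline structure appears exactly as in the real
cohort — the low responders differ from both high responders and the
COPD group, while COPD vs high responders shows **no** significant genes,
because both draw from the same latent responsiveness regime.

The same stages are available as subcommands of the `saeindex` console
script (`simulate`, `signature`, `index`, `classify`, `contrast`,
`kfold`, `run`, `report`); `saeindex run --config run.yaml` drives
everything from one YAML file.

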