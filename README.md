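# subpls

Partial least squares correlation (PLSC) between subcortical functional
connectivity and mood-symptom profiles in depression, with permutation
significance, bootstrap reliability, cross-cohort replication, and prediction
of antidepressant treatment outcome from subject-level connectivity scores.

The package is written for researchers analysing resting-state fMRI cohorts
with clinical ratings: each subject contributes a functional-connectivity
(FC) profile — the Fisher-z Pearson correlations between the BOLD time series
of `d = 54` subcortical parcels, vectorized to the `d(d-1)/2 = 1431` unique
edges — and a 37-item mood profile (10 PANAS positive-affect items, 10 PANAS
negative-affect items, the 17 HRSD-17 depression items). Because clinical
MRI datasets of this kind are rarely public, a first-class synthetic-cohort
generator with a planted latent component makes every stage testable end to
end.

## The model

With `X` (n x p FC edges) and `Y` (n x q items) column-standardized, PLSC
decomposes the cross-covariance by SVD:

    R = Yᵀ X / (n − 1) = U S Vᵀ

Each latent component (LC) pairs a mood salience `u_k` and an FC salience
`v_k` with singular value `s_k`; the k-th LC explains `s_k² / Σ s²` of the
squared cross-covariance. Subject scores are projections of the standardized
blocks onto the saliences; loadings — the interpretable quantity — are
Pearson correlations between original variables and component scores.

Inference by resampling:

* **Permutation test** — rows of `Y` permuted, model refitted, null singular
  values compared rank for rank; `p = (1 + #{null ≥ observed}) / (1 + B)`.
* **Bootstrap ratio (BSR)** — subjects resampled with replacement, each
  solution Procrustes-aligned (singular-value-scaled, mood-side rotation
  applied to both blocks) to the observed one; BSR = observed scaled salience
  / bootstrap SD, a z-like reliability index (`|BSR| > 2` ≈ p < 0.05).
  Percentile bootstrap CIs on the loadings flag significant variables.
* **Replication** — an independent cohort is standardized with its own
  statistics and projected onto the training saliences; loading similarity
  and predicted-vs-observed score agreement quantify generalization.
* **Prediction** — treatment outcome after 8 weeks (percentage HRSD-17
  reduction; response = strictly >50% reduction; remission = posttreatment
  total ≤ 7) is modelled by stepwise linear/logistic regression on the LC1
  FC score plus clinical candidates, with ROC/AUC evaluation.

## Worked example

Run the whole pipeline on a synthetic main cohort (n = 135) with an
independent replication cohort (n = 74) sharing the same planted component:

```python
from subpls import PipelineConfig, run_pipeline

config = PipelineConfig(seed=1, B_perm=1000, B_boot=1000,
                        simulate={"n": 135, "structure_seed": 7},
                        replication_simulate={"n": 74, "structure_seed": 7})
summary = run_pipeline(config, "demo_out")
```

prints (from `demo_out/summary.json`):

```
"k": 37,
"explained_cov_lc1": 0.4063159773374834,
"p_lc1": 0.000999000999000999,
"n_significant_components": 1,
"n_reliable_edges": 95,
"n_robust_edges": 70,
"fc_loading_similarity": 0.405100689910758,
"mood_loading_similarity": 0.9723245104527518,
"auc_remission": 0.6950113378684807,
"remission_rate_pct": 50.0
```

Reading: 37 latent components were extracted and only the first survived the
permutation test (p = 1/1001, the smallest value B = 1000 permutations can
resolve), explaining 40.6% of the FC-mood cross-covariance. 95 edges are
reliable (`|BSR| > 2` with loading CI excluding 0) and 70 survive the
stricter robust tier (`|BSR| > 3`, top 5% by absolute loading). Projected
onto the 74-subject replication cohort, the mood loading profile replicates
almost exactly (r = 0.97) while the FC loading profile replicates moderately
(r = 0.41 — the FC side has 1431 noisy coordinates against 37). Among
completers, half remit, and the logistic remission model on the LC1 FC score
classifies with AUC = 0.70.

The same stages are available as a CLI (`subpls simulate | fc | fit |
permute | bootstrap | replicate | predict | run | report`), e.g.

```
subpls simulate --n 135 --seed 1 --out data/
subpls fit --fc data/fc.tsv --symptoms data/subjects.csv --out model/
```

## Layout

| module | contents |
| --- | --- |
| `subpls.connectivity` | ROI time series → scrubbing → Fisher-z FC profiles |
| `subpls.pls` | data blocks, residualization, PLSC fit, scores, loadings |
| `subpls.resampling` | permutation test, bootstrap BSR/CIs, edge selection |
| `subpls.replication` | external projection, cross-cohort comparison |
| `subpls.prediction` | outcome records, stepwise models, ROC evaluation |
| `subpls.synthetic` | planted-component cohort and time-series generators |
| `subpls.io` | formats, configuration, end-to-end pipeline |
| `subpls.cli` | command-line interface |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
numerical choices.
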