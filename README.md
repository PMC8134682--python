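# iciscope

Immune-cell-infiltration (ICI) characterization and scoring for bulk tumor
expression cohorts.

Bulk tumor transcriptomes mix malignant cells with infiltrating immune
cells, and the pattern of that infiltrate carries prognostic and
therapy-predictive information — in melanoma especially, where inflamed
tumors respond better to checkpoint blockade. `iciscope` implements the
full analysis arc for quantifying that pattern and condensing it into a
single per-sample statistic:

1. **Deconvolution** — per-sample immune-cell fractions by nu-support-vector
   regression against a cell-type signature matrix (the CIBERSORT
   algorithm), plus ssGSEA immune/stromal scores (the ESTIMATE approach).
2. **Immune subtyping** — resampling-based consensus clustering of the
   fraction profiles, with delta-area selection of k and labels
   canonicalized by immune score.
3. **Signature discovery** — empirical-Bayes moderated-t DEGs among
   subtypes, partitioned into signatures A (immune-activation axis) and B
   (its complement), pruned Boruta-style with shadow-feature random
   forests.
4. **The ICI score** — for each sample,

   ```
   ICI score = PC1(signature A) − PC1(signature B)
   ```

   where PC1(·) is the first principal component of the z-scored signature
   block projected onto samples. Higher scores mean a more immune-active
   tumor.
5. **Evaluation** — maximally selected log-rank cutoff, Kaplan–Meier/Cox
   survival contrasts and stratified forest tables, tumor-mutation-burden
   and per-gene mutation-frequency statistics (Yates-corrected chi-square),
   preranked GSEA, and therapy-response ROC/rate tables.

A first-class synthetic-cohort generator plants known immune subtypes,
survival links, mutation enrichments and response labels, so every stage is
testable against ground truth. The package is a library first — the
`examples/` scripts show each capability — with a thin `iciscope` CLI for
shell use.

## Worked example

```python
from iciscope.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(seed=11, n_samples=150, reps=60, boruta_iter=20)
result = run_pipeline(config, "out/")
print(result.manifest["summary"])
```

which prints (abbreviated from `examples/03_ici_score_and_survival.py`):

```
DEGs: 120  (signature A: 25, B: 31)
ICI score cutoff: 5.471
log-rank p (high vs low): 4.54e-09
Spearman(ICI score, true immune fraction): 0.792
```

Read: 120 genes separate the three immune subtypes; the score built from
them ranks samples almost identically to the planted immune-cell content
(Spearman 0.79), and splitting at the maximally selected cutoff separates
overall survival decisively (log-rank p ≈ 5e-9) — the generator gives
immune-rich samples a lower hazard, and the pipeline recovers that link
from expression alone.

Every stage is also available piecemeal:

```python
import iciscope as ic
from iciscope.simulate import simulate_cohort

cohort = simulate_cohort(n_samples=60, seed=42)
fractions = ic.svr_deconvolve(cohort.expression, cohort.signature)
```

See `examples/` for deconvolution accuracy, consensus subtyping,
mutation contrasts, and enrichment/response evaluation, and
`docs/methods.md` for models, defaults and limitations.

## CLI

```bash
iciscope simulate --out cohort/ --seed 3 --n-samples 300
iciscope deconvolve --bulk cohort/expression.tsv --signature cohort/signature.tsv --out fractions.tsv
iciscope cluster --input fractions.tsv --k 3 --reps 1000 --seed 7 --out clusters/
iciscope run --out full_run/ --seed 11
```

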