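# oncostage

Stage-stratified biomarker discovery for cancer transcriptomes: moderated
stagewise linear models, stage-salient differential expression, monotone
progression trends, and downstream diagnostic / prognostic modelling — with
a synthetic-data generator that plants ground truth so the whole chain is
testable end to end.

## The problem

Bulk RNA-seq cohorts such as TCGA COADREAD annotate each tumor with a
discrete AJCC stage (I–IV) next to a set of normal-tissue controls. Most
differential-expression analyses collapse the tumors into one group and
lose the progression axis. `oncostage` keeps the stages apart and asks
three ordered questions:

1. **Which genes change with cancer at all?** Per gene, a weighted linear
   model over the five groups,

   *y* = α + β₁x₁ + β₂x₂ + β₃x₃ + β₄x₄,

   where the xᵢ are stage indicators, α is the control baseline and the βᵢ
   are stagewise log₂ fold-changes. Residual variances are shrunk toward a
   pooled prior (df *d₀*, variance *s₀²*) estimated by the standard moments
   method on log variances, giving moderated t and F statistics on
   *d₀* + df degrees of freedom; F-test p-values are Benjamini–Hochberg
   adjusted.
2. **Which genes are salient to one stage?** A cell-means fit feeds two
   contrast families: stage-vs-control and the six between-stage pairs.
   A gene whose maximal |lfc| exceeds 2 is assigned to that stage, and is
   *stage-salient* when the adjusted stage-vs-control p < 0.001 and all
   three between-stage p-values involving its stage are < 0.05. Sparse
   stages are ranked by `pval_pdt`, the product of those three p-values
   (three p-values at 0.05 multiply to the 1.25×10⁻⁴ cutoff used for
   stage III).
3. **Which genes track progression?** A second model treats stage as a
   number, *y* = aX + b with X ∈ {0..4}; genes whose five group means are
   strictly ordered are monotonically expressed genes (MEGs), significant
   at adjusted slope p < 0.05. Significant MEGs that are also stage-salient
   are the *progression-significant* genes.

The discovered panels then feed two models: a cancer-vs-normal screening
classifier (random forest by default, with the full confusion-matrix
metric suite), and a Cox proportional-hazards risk score,

Risk score = Σᵢ βᵢ · geneᵢ,

built by univariate screening plus backward-AIC selection, evaluated by
median-split Kaplan–Meier curves, the log-rank test and Harrell's C-index.

Count-like data are transformed to log₂ counts-per-million with
per-observation precision weights from a lowess mean–variance trend before
any model is fitted. The implementation is validated against Bioconductor
limma's voom/eBayes on a frozen fixture (see `tests/data/`).

## Worked example

```python
from oncostage import (SimConfig, generate_expression_dataset,
                       generate_survival_outcomes, run_stagewise_analysis,
                       univariate_cox_screen, fit_cox_backward_aic,
                       compute_risk_score, stratify_and_km)

cfg = SimConfig(n_per_group=50, n_null=400, n_global_de=20,
                n_stage_salient=40, n_monotone_up=20, n_monotone_down=10,
                n_prognostic=3, seed=7)
expr, truth = generate_expression_dataset(cfg)
res = run_stagewise_analysis(expr)
print(res.summary())
```

```
Stagewise biomarker discovery run
========================================
genes 493 -> 277 (216 below sd threshold); samples 250 -> 250 (0 NA-stage tumors removed)
significant linear-model genes: 153
stage-salient genes: I: 10, II: 10, III: 9, IV: 32
genes eliminated by the |lfc| filter: 195
MEGs: 89 (18 up, 71 down); significant: 89
progression-significant genes: 25
diagnostic feature space: 109 genes
```

All 40 planted stage-salient genes are recovered; stage IV reports extra
genes because the planted monotone genes legitimately peak there, and the
MEG count exceeds the 30 planted trends because stagewise library-content
imbalance induces weak compensatory CPM trends in other genes (see
`docs/methods.md`). The prognostic stage on the same cohort:

```python
surv = generate_survival_outcomes(expr, truth, cfg)
X = expr.values.T.loc[surv.index]
screen = univariate_cox_screen(X, surv, truth.index[truth.planted_class == "prognostic"])
model = fit_cox_backward_aic(X, surv, screen.index[screen.significant])
scores = compute_risk_score(model, X)
strat = stratify_and_km(scores, surv)
print(model.summary())
```

```
Cox risk-score model
========================================
risk score = 0.55683 * SIM00491 + 0.45197 * SIM00492 + 0.58603 * SIM00493
model p-value (LR test): 1.66e-20
concordance index:       0.726
  SIM00491     beta=+0.5568  p=2.46e-09
  SIM00492     beta=+0.4520  p=2.54e-07
  SIM00493     beta=+0.5860  p=4.1e-10
```

The three planted prognostic genes (true β = 0.5 each) are recovered with
coefficients 0.45–0.59 and the high/low split separates survival at
log-rank p ≈ 3×10⁻¹⁵.

A command-line surface wraps the same chain:

```sh
oncostage simulate --config cfg.yaml --out fixtures/
oncostage run --expr fixtures/expression.tsv --clinical fixtures/clinical.tsv --out results/
oncostage screen --expr ... --clinical ... --panel results/feature_panel.txt --out screen/
oncostage prognosis --expr ... --clinical ... --genes candidates.txt --out prog/
```

Real cohorts are ingested from firebrowse-style RSEM expression TSVs
("Hybridization REF" barcode header; sample type parsed from the TCGA
barcode) and clinical TSVs carrying `pathologic_stage` (sub-stages A/B/C
collapse into the parent stage) and overall-survival fields.

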