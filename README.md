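# prognosig

Multi-cohort discovery and validation of prognostic gene-expression
signatures for survival transcriptomics.

## The problem

Resected pancreatic ductal adenocarcinoma (PDAC) — like many cancers —
shows wide variation in survival that clinical stage and grade capture
poorly. A recurring analysis pattern in the field derives a **gene
signature** from expression profiles: screen genes whose expression
stratifies survival in a training cohort, compress the survivors into a
sparse classifier, and demand that the predicted risk groups separate
survival in fully independent validation cohorts. `prognosig`
implements that protocol as a tested, reusable library for
bioinformaticians and biostatisticians, together with the permutation
machinery needed to judge whether a signature beats the multitude of
"random signatures" such pipelines can produce.

## The method

Given gene × sample log2 abundance matrices and per-sample survival
(time in months, event indicator, optional TNM stage and grade):

1. **Candidates** — moderated paired t-test on matched tumour/normal
   pairs; the gene-wise variances are shrunk via the empirical-Bayes
   posterior s̃²_g = (d₀s₀² + df·s²_g)/(d₀ + df), and genes with
   BH-adjusted p < 0.01 and |log2 FC| > 0 are kept.
2. **Merging** — two training cohorts are combined by
   distance-weighted discrimination: the batch direction **w**
   minimising Σᵢ 1/rᵢ + C Σᵢ ξᵢ (rᵢ = yᵢ(wᵀxᵢ + b) + ξᵢ, ‖w‖ ≤ 1) is
   removed by zeroing each cohort's mean projection on **w**.
3. **Screen** — each candidate is median-dichotomised; genes with Cox
   Wald P < 0.05 (Breslow partial likelihood, Newton–Raphson) survive.
4. **Classifier** — nearest shrunken centroids: deviations
   d_ik = (x̄_ik − x̄_i)/(m_k(s_i + s₀)) are soft-thresholded at Δ chosen
   by leave-one-out cross-validation; the genes left with nonzero
   deviations are the signature.
5. **Validation** — Kaplan–Meier curves, log-rank χ², hazard ratios
   (optionally stage/grade-adjusted) and 20-month confusion accuracy on
   independent cohorts; plus a random-signature permutation study with
   per-cohort BH adjustment and gene inclusion-frequency ranking.

A synthetic-cohort generator with a planted prognostic module (latent
risk u ~ N(0,1) shared by the planted genes, exponential survival with
hazard ∝ exp(βu), independent censoring, per-cohort batch shifts) gives
every stage a recoverable ground truth. See `docs/methods.md` for the
full model descriptions and design choices.

## Worked example

```python
from prognosig import (PrognosticSignatureModel, SimulationConfig,
                       CohortSpec, simulate_cohorts)

cfg = SimulationConfig(
    n_genes=500, n_prognostic=10, beta=1.0,
    cohorts=(CohortSpec("tr_a", 100, 0.0), CohortSpec("tr_b", 100, 2.0),
             CohortSpec("va", 100, -1.0)),
    seed=7,
)
exprs, clins, truth = simulate_cohorts(cfg)

model = PrognosticSignatureModel.from_cohorts(
    exprs["tr_a"], exprs["tr_b"], clins["tr_a"], clins["tr_b"])
results = model.fit()
print(results.summary())

report = results.validate(exprs["va"], clins["va"], adjust=("stage", "grade"))
print(f"validation HR = {report['cox'].hr:.2f}, "
      f"log-rank p = {report['logrank_p']:.2e}, "
      f"20-month accuracy = {report['confusion'].accuracy:.2%}")
```

Output (seed 7):

```
                Prognostic signature discovery
==============================================================
Training samples:            200
Candidate genes:             500
Prognostic genes (Wald P < 0.05): 24
Signature size:              23
Shrinkage threshold Delta*:  0.0670
LOOCV accuracy:              0.695
Resubstitution accuracy:     0.715
Risk classes:                time <= 20 months = high
--------------------------------------------------------------
Top prognostic genes (by Wald P):
gene              HR     beta      p_wald
G0411          2.971    1.089    3.82e-10
G0384          2.527    0.927    5.02e-08
G0410          0.412   -0.888    1.85e-07
...
==============================================================
validation HR = 2.28, log-rank p = 1.23e-03, 20-month accuracy = 58.00%
```

All ten planted genes pass the screen (24 genes kept of 500) and all
ten sit in the 23-gene signature; the predicted risk groups separate
the held-out cohort's survival with a hazard ratio of 2.3. Note the
top genes split into both directions — the generator plants up- and
down-regulated prognostic genes, mirroring signatures whose low
expression marks poor outcome.

The same pipeline is scriptable from the shell:

```bash
prognosig simulate --seed 7 --out sim/
prognosig merge --expr-a sim/tr_a_expression.tsv --expr-b sim/tr_b_expression.tsv --out merged.tsv
prognosig select --expr merged.tsv --clinical train_clin.tsv --out prognostic.tsv
prognosig train  --expr merged.tsv --clinical train_clin.tsv --genes genes.txt --out model.json
prognosig predict --model model.json --expr sim/va_expression.tsv --out risk.tsv
prognosig validate --risk risk.tsv --clinical sim/va_clinical.tsv --adjust stage,grade --out report.json
```

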