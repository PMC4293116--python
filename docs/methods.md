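# Methods

`prognosig` implements a multi-cohort protocol for discovering and
validating prognostic gene-expression signatures in survival
transcriptomics, of the kind used to stratify resected pancreatic
ductal adenocarcinoma (PDAC) patients into low- and high-risk groups.
This note describes the statistical machinery, the choices made where
the design was genuinely open, and what the synthetic studies used by
the tests do and do not demonstrate.

## The protocol

1. **Candidate genes.** Matched tumour/normal pairs are compared with a
   moderated paired t-test; genes with BH-adjusted p < 0.01 and
   |log2 fold change| > 0 (strict inequalities) form the candidate
   universe. Probe-level matrices are first collapsed to one row per
   gene symbol, keeping the probe set with the largest sample variance
   (n−1 denominator; ties broken toward the lexicographically smallest
   probe ID).
2. **Training-cohort assembly.** Two training cohorts are merged by
   distance-weighted discrimination (DWD): the direction `w` that best
   separates the cohorts is estimated, and each cohort is translated
   along `w` so its mean projection is zero. Only the one-dimensional
   batch subspace is modified.
3. **Prognostic screen.** Each candidate gene is median-dichotomised
   (ties to the low group) and a univariate Cox model with the binary
   high-expression indicator is fitted; genes with Wald P < 0.05 are
   kept. No multiplicity correction is applied at this stage — the
   screen is a recall-oriented filter ahead of the classifier.
4. **Classifier.** A nearest-shrunken-centroid (NSC) model is trained on
   the screened genes against observed risk classes (survival at or
   below 20 months = high risk). The shrinkage threshold Δ is chosen by
   leave-one-out cross-validation over a 30-point grid on
   [0, max |d_ik|], taking the **largest** Δ attaining the minimum error
   (most parsimonious among the best). The genes with a nonzero shrunken
   deviation at Δ\* are the signature.
5. **Validation.** The classifier predicts risk groups in held-out
   cohorts; groups are compared by Kaplan–Meier curves, the log-rank
   test, univariate Cox (and Cox adjusted for TNM stage IA/IB/IIA vs
   IIB/III/IV and grade 1/2 vs 3/4), and a 2×2 confusion table against
   the 20-month survival dichotomy.
6. **Permutation null.** Random gene pools of fixed size are pushed
   through steps 3–5; each run is scored per validation cohort by the
   log-rank chi-square of its predicted groups, BH adjustment is applied
   per cohort across runs, and genes are ranked by their inclusion
   frequency among the runs significant in every cohort.

## Statistical components

**Moderated t.** The gene-wise variances of the paired differences are
shrunk toward a prior: s̃²_g = (d0·s0² + df·s²_g)/(d0 + df), with
(d0, s0²) estimated by moment matching on log s² (digamma/trigamma
closed forms, trigamma inverted by Newton iteration). The statistic
lfc_g / sqrt(s̃²_g / n) is referred to Student t with d0 + df degrees of
freedom (normal when d0 = ∞). d0 is reported as infinite when the
empirical variance of log s² does not exceed its pure sampling variance
ψ′(df/2) beyond a one-sided 95% allowance — without that allowance,
estimation noise alone would report a large finite d0 on perfectly
homogeneous variances. The implementation agrees with Bioconductor
limma's eBayes to machine precision on shared input (tested).

**Cox models.** All Cox fitting maximises the Breslow partial likelihood
by Newton–Raphson with step-halving (convergence |Δβ| < 1e−8, ≤ 50
iterations); |β| > 15 is flagged as a monotone likelihood (separation)
rather than reported as a number. The screening stage vectorises the
one-binary-covariate case across genes: at each distinct event time the
risk set reduces to counts of high-group samples, so thousands of genes
fit in milliseconds. Wald confidence intervals are exp(β ± 1.96·se).
Efron tie handling is not implemented; on tie-free data the estimates
match lifelines' CoxPHFitter (tested).

**DWD.** The primal problem min Σ 1/r_i + C Σ ξ_i with
r_i = y_i(wᵀx_i + b) + ξ_i > 0, ξ_i ≥ 0, ‖w‖ ≤ 1 is solved after
eliminating the slacks in closed form: given the margins m_i, the
optimal contribution of sample i is 1/m_i when m_i ≥ 1/√C and
2√C − C·m_i otherwise, leaving a smooth convex objective in (w, b)
minimised by SLSQP under the norm constraint. Because the objective
depends on w only through wᵀx_i, the solve runs exactly in the span of
the samples (dimension ≤ n); an optional PCA truncation is available
for very wide matrices but is off by default. The penalty defaults to
C = 100 / (median pairwise inter-sample distance)². When the two
batches are indistinguishable the separating direction is undefined;
the fit falls back to the leading principal component with a warning,
which still yields the correct "common translation" behaviour.

**NSC.** d_ik = (x̄_ik − x̄_i)/(m_k(s_i + s0)) with
m_k = √(1/n_k + 1/n) (the √(1/n_k − 1/n) variant is selectable), s_i
the pooled within-class standard deviation (divisor n − K), and s0 the
median of the s_i. Soft-thresholding |d_ik| by Δ gives the shrunken
centroids; prediction minimises Σ_i (x_i − x̄′_ik)²/(s_i + s0)² −
2 log π_k with empirical priors (uniform optional) and ties broken
toward the first class in model order.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `padj_cut`, `lfc_cut` | 0.01, 0 | DE filter (strict inequalities) |
| `alpha` | 0.05 | Wald-P threshold of the prognostic screen |
| `risk_threshold_months` | 20 | survival dichotomy for training labels and accuracy; `"median"` uses the median observed time |
| `grid_size` | 30 | LOOCV shrinkage grid resolution |
| `C` | 100/median²   | DWD slack penalty |
| `pool_size` | 225 | random-signature pool size |

## Cross-cohort alignment at prediction time

Validation cohorts generally sit at a different location than the
training frame (platform offsets; and the DWD convention itself
translates the training data along `w`). `PrognosticSignatureResults`
therefore centres each validation cohort gene-wise onto the
classifier's overall centroid before prediction — the same move
cross-platform subtype classifiers (e.g. PAM50-style median centring)
make. The cost is that a cohort whose outcome mix is extremely skewed
loses part of its class signal to the centring; the benefit is that
predictions are invariant to any cohort-wide location offset (tested).
The bare `predict_nsc` operation performs no centring.

## The synthetic-data generator

Each sample carries a latent risk score u ~ N(0,1); every planted
prognostic gene adds ±u (random sign per gene) to its log2 expression,
and survival is exponential with hazard (1/baseline_scale)·exp(β·u),
censored by an independent exponential clock. A single shared factor —
rather than independent per-gene signals — is deliberate: prognostic
modules are co-expressed programmes of one underlying process, and with
independent signals the genes omitted from a univariate model act as
frailty, attenuating every marginal hazard ratio far below its nominal
value (measured: ~3/10 vs ~9/10 planted genes detectable at n = 100).
Defaults: baseline_scale = 20/ln 2 ≈ 28.9 months (20-month median
survival, typical of resected PDAC), censor_rate = 0.01/month,
noise_sd = 1 log2 unit, β = 1, de_lfc = 2 with 42 tumour/normal pairs.
Stage and grade are drawn with a mild logistic link (slope 0.5) to u so
that multivariable adjustment is exercised meaningfully. Batch effects
are additive per-cohort mean shifts — exactly the structure DWD
removes; the generator does not emulate variance differences between
platforms, probe-level artefacts, or informative censoring, so passing
tests demonstrate correctness of the machinery under proportional
hazards with location-only batch effects, not robustness to every
failure mode of real microarray meta-analysis.

## Numerical and design notes

- Training risk classes from the 20-month rule follow the recorded time
  regardless of censoring (the protocol's literal rule); an option
  excludes patients censored before the threshold, whose true class is
  unknown.
- With imbalanced training classes and weak gene pools, the NSC
  discriminant is dominated by the empirical priors and can predict a
  single class for every sample; such runs are flagged degenerate in
  the permutation study and never enter BH denominators.
- Permutation-study runs are seeded from (master seed, run index), so a
  study can be sharded across workers and recomposed exactly
  (`summarize_study`).
- In the permutation study the raw per-cohort significance fraction is
  only binomially calibrated when runs rarely reuse the same
  chance-selected genes; the test-suite study therefore uses a universe
  (2000) much larger than the pool (50), and cohort sizes of 60–80 —
  a deliberate scale-down of the full protocol that keeps the study's
  statistical behaviour while running on a desktop.
- LOOCV on balanced random labels is pessimistic (the left-out sample's
  class becomes the training minority); error rates near or above 50%
  on null data are expected, not a defect.

## Known limitations

- Only two-batch DWD merging is supported; multi-cohort merging is
  sequential pairwise and approximate.
- The permutation study at the published scale (millions of
  signatures) requires sharding; defaults target desk-scale studies.
- Breslow ties only; heavy tie structures will differ slightly from
  Efron-based software.
- The 20-month accuracy metric inherits the protocol's literal
  treatment of early-censored patients.
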