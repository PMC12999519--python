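# convorg

Tools for asking whether genetically distinct forms of a neurodevelopmental
condition **converge** on shared transcriptomic changes as in-vitro cortical
differentiation progresses — and for tracing that convergence to an upstream
module of transcriptional regulators.

The package targets cohorts like multi-form hiPS-cell cortical-organoid
studies: bulk RNA-seq of many donors across several differentiation days,
where each donor carries one of several distinct mutations (or is an
unaffected control). It implements the full analysis chain:

- **simdata** — synthetic cohorts with planted ground truth: negative-binomial
  counts (Var = μ + αμ²) driven by module latent factors, nested
  individual/line/differentiation effects, per-form log2 effects whose shared
  component follows a *convergence schedule* s_d (effect = (1−s_d)·specific +
  s_d·shared), CNV dosage shifts, and a regulator module negatively coupled to
  downstream modules. Companion generators emit a single-cell reference, an
  IP–MS bait×prey table, a CROP-seq experiment and regulator→target
  annotations.
- **preprocess** — low-expression filtering (≥10 reads in ≥30 % of a group's
  samples), TMM normalization to log2 CPM, sample-network connectivity
  outliers (z < −2 within day × form), covariate residualization,
  reproducibility correlations and REML variance fractions.
- **diffexpr** — per-gene linear mixed models (single random intercept,
  profiled REML vectorized across genes), per-day form-vs-control Wald
  contrasts with BH correction, inverse-variance fixed-effect meta-analysis
  across forms, CNV dosage summaries and peak-expression days.
- **convergence** — condition (form×day) logFC matrices, Ward.D2 clustering
  on Euclidean distances of Spearman correlations, multiscale bootstrap
  support (BP and the approximately-unbiased AU), cophenetic/Rand concordance
  across clustering choices, and the per-day correlation trend test
  (ANOVA + Tukey HSD over all C(F,2) form-pair correlations per day).
- **comodules** — signed co-expression networks (a_ij = ((1+cor)/2)^β),
  scale-free soft-threshold selection (R² > 0.8), topological overlap,
  form-balanced resampled consensus (median TOM dissimilarity, ≥4 samples
  per form per iteration), simplified hybrid tree cut with kME
  adoption/pruning, eigengenes/kME, module–trait association with the signed
  adjusted-R convention, spline trajectory tests, and a light-weight
  preservation Z.
- **regnet** — the kME-weighted module→module regulation score
  (Σ kME of regulated genes in the downstream module / module size) with the
  mean + 1 SD edge threshold, regulator–target correlations, and risk-gene
  tables for downstream modules.
- **enrich** — two-sided Fisher/hypergeometric gene-set enrichment and
  EWCE-style specificity bootstrap with the add-one p rule.
- **deconv** — marker-signature NNLS deconvolution onto the simplex and
  adjusted-logit (a = 0.001) mixed-model proportion tests.
- **ppi** — IP–MS network connectedness (mean bait×member logFC, zeros for
  undetected pairs) against a size-matched permutation null.
- **crispr** — CROP-seq cell QC (>200 features, <10 % mito), gRNA→cell
  assignment (UMI ≥ 10, unique target), knockdown ratios vs non-targeting
  controls, and moderated pseudobulk differential expression.

## Worked example

Run the whole pipeline on a synthetic cohort from the command line:

```
convorg --seed 3 --outdir run all
```

or drive it from Python:

```python
from convorg.simdata import SimConfig, simulate_cohort
from convorg.preprocess import filter_low_expressed, tmm_normalize
from convorg.diffexpr import fit_cohort_lmm, de_all_contrasts
from convorg.convergence import condition_logfc_matrix, convergence_trend

cohort, truth = simulate_cohort(SimConfig(seed=3))
expr = tmm_normalize(filter_low_expressed(cohort))
fit = fit_cohort_lmm(expr, cohort.samples)
de = de_all_contrasts(fit, cohort.samples)
rho, anova, tukey = convergence_trend(condition_logfc_matrix(de))
print(rho.groupby("day")["rho"].mean())
print(f"ANOVA F={anova['F']:.1f} p={anova['p']:.2g}")
```

prints (day ordered 25 → 100):

```
day
100    0.257971
25     0.083500
50     0.122708
75     0.177800
Name: rho, dtype: float64
ANOVA F=242.2 p=3.3e-55
```

The mean cross-form correlation of differential-expression signatures rises
from ≈0.08 at day 25 to ≈0.26 at day 100 — the planted convergence schedule
(0.1, 0.3, 0.6, 0.9) read back out through the full filtering, normalization,
mixed-model and correlation machinery, with the ANOVA confirming the day
effect on the 36 form-pair correlations per time point.

The run directory also contains the consensus module labels and eigengenes,
the module regulation graph (the mean + 1 SD score threshold lands near 0.29
on default cohorts), deconvolved proportions, IP–MS connectedness z-scores
and CRISPRi knockdown ratios, plus a `report.json` summarizing every stage.

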