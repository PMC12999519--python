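# Methods

This note documents the models and numerical choices behind `convorg`, in
the order the pipeline runs them, and states what the synthetic-data
generator does and does not emulate.

## Synthetic cohort model

`simdata.simulate_cohort` draws counts `y_gs ~ NB(mu_gs, alpha)` with
`Var = mu + alpha mu^2` (gamma–Poisson mixture; `alpha -> 0` recovers
Poisson). The log2 mean is

```
log2 mu_gs = base_g + slope_g * x_d + sum_m L_gm z_ms + effect(g, form_s, d)
           + log2(dosage) * [g in CNV(form_s)] + u_ind(g) + u_line(g) + u_diff(g)
```

- `base_g ~ N(5, 1.5)` log2 units (log-normal means), `slope_g ~ N(0, 0.3)`
  against normalized day index `x_d`.
- Module structure: each of 6 planted modules (40–80 genes) loads on a
  per-sample latent factor `z ~ N(0, 1)` with loadings `U(0.7, 1.3)`. The
  three "downstream" modules share a negative coupling (default −0.6) with
  the "upstream" regulator module, so regulator–target correlations are
  predominantly negative.
- Form effects: `effect = (1 - s_d) u(g, f) + s_d v(g)` with
  `u, v ~ N(0, 0.2)` log2 units and `s_d` the convergence schedule
  (default 0.1, 0.3, 0.6, 0.9 for days 25/50/75/100). The cross-form
  correlation of planted effects is therefore
  `s^2 sigma_v^2 / (s^2 sigma_v^2 + (1-s)^2 sigma_u^2)`, monotone in `s`.
  The 0.2 scale is deliberate: dense per-gene effects much larger than that
  (CNV-scale, ~0.5) would make DE structure dominate the co-expression
  topology, a regime real cohorts do not show — module co-variation is far
  stronger than per-form differential expression.
- Nested effects are *gene-specific* intercepts (individual 0.3, line 0.15,
  differentiation 0.15 log2 units). Scalar per-sample intercepts would be
  pure depth shifts that CPM normalization cancels exactly; gene-specific
  ones create the real within-individual correlation the mixed model and
  the variance-partition stage are built for.
- Cohort shape: 9 affected forms × 3 individuals plus 25 control
  individuals (× lines × differentiations × 4 days). The control-heavy
  design matters: every form-vs-control logFC shares the control mean, so
  control estimation noise induces a correlated floor under the cross-form
  correlations. With ~50 control samples per day that floor is ~0.06; with
  6 it would be ~0.4 and mask the early part of the schedule.
- CNV "regions" are gene sets (10 genes for each of 2 forms, dosage 0.5 by
  default); coordinates are out of scope.

What the generator does **not** emulate: gene–gene correlation beyond the
module factors, GC/length biases, batch-by-day interactions, isoform
effects, and real dropout patterns in the single-cell generators. Passing
recovery tests therefore demonstrate correctness of the estimators under a
well-specified generative model, not robustness to every artefact of real
data.

## Preprocessing

Low-expression filtering keeps a gene when ≥30 % of a group's samples have
≥10 reads (inclusive at the boundary; the rule is applied per day by
default and is idempotent). TMM factors follow the published
weighted-trimmed-mean-of-M-values recipe: reference = sample whose 75th
percentile of library-scaled counts is closest to the mean, 30 % M-trim,
5 % A-trim, inverse asymptotic-variance weights, factors rescaled to
geometric mean 1; log2 CPM uses effective library sizes and pseudocount 0.5.
The implementation agrees with edgeR's `calcNormFactors` to ~1e-8 on dense
matrices (verified in the test suite via Rscript).

Outliers are flagged within day × form by standardized network
connectivity `z = (k - mean k)/sd k`, `k_s = sum_t cor(s, t)` (Pearson on
log2 CPM by default), single pass, `z < -2`; iteration to a fixed point is
available behind a flag but off by default, since the published procedure
does not state iteration.

Variance fractions use a direct multi-start Nelder–Mead REML on
`V = sum_k s2_k Z_k Z_k' + s2_e I` (categorical terms as random
intercepts, continuous terms as fixed effects whose contribution is the
variance of the fitted component). A general-purpose mixed-model fitter
was not reliable on small crossed designs (non-convergence at variance
boundaries), so the estimator is implemented directly and cross-checked
against an independent optimization route in the tests.

## Differential expression

Each gene is fit with a linear mixed model with one random intercept
(individual by default; line or differentiation can be substituted).
Because every gene shares the design and grouping,
`V = I + lambda Z Z'` is block diagonal and all REML quantities reduce to
group sums, so the likelihood is profiled on a log-spaced lambda grid
(97 points plus exactly 0) for all genes simultaneously; `lambda = 0`
collapses exactly to OLS. Wald t-tests use the residual-df approximation
`df = n - p - q + 1`. This trades Satterthwaite accuracy for desk-scale
runtime; type-I calibration at alpha = 0.05 is verified by simulation.
Fixed effects default to form×day cell means plus sex, batch, ancestry PCs
and sequencing PCs (centered); the contrast for form F at day d is
`cell[F@d] - cell[control@d]`, BH-corrected within each (form, day).

The cross-form meta-analysis is the fixed-effect inverse-variance model:
`beta = sum(w b)/sum w`, `w = 1/se^2`, `se = 1/sqrt(sum w)`, two-sided
normal p, BH per day.

## Convergence statistics

Conditions are clustered by Ward linkage on Euclidean distances between
rows of the Spearman correlation matrix; scipy's `ward` on distance input
carries the squared-increment (ward.D2) semantics, and the classic-Ward
variant (`ward.D`) is obtained by running on sqrt-distances and squaring
the heights. Multiscale bootstrap resamples `ceil(r n)` genes at scales
0.5–1.4, records per-cluster frequencies `BP_r`, and fits
`Phi^-1(1 - BP_r) = v sqrt(r) + c/sqrt(r)` by weighted least squares
(delta-method weights), giving `AU = 1 - Phi(v - c)`; `BP_r` in {0, 1} is
clamped to 1/(2B) before the probit, and the bootstrap budget is split
evenly across scales. The per-day trend test computes Spearman rho for
every unordered form pair (C(F,2) per day), a one-way ANOVA of rho by day
on untransformed rho (a Fisher-z flag exists), and Tukey HSD via the exact
studentized-range distribution. Minkowski distance in the concordance
sweep uses p = 3 so it is distinct from Euclidean.

## Consensus networks and modules

Signed adjacency `((1 + cor)/2)^beta` with the soft threshold chosen as
the smallest power whose scale-free fit index `-sign(slope) R^2` reaches
0.8 (10 connectivity bins, log–log regression). TOM follows

```
TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
```

and the consensus is the element-wise median of `1 - TOM` over
form-balanced bootstrap iterations (resampling with replacement within
each form to the original count, re-drawn until ≥4 distinct samples per
form survive). The per-iteration network path runs in float32: the median
is insensitive to last-digit rounding of individual entries, and the
matrix product dominates runtime. The float64 `tom_dissimilarity` is kept
exact (1e-10 against a brute-force triple loop).

Module detection is a simplified hybrid tree cut on the average-linkage
tree of the consensus dissimilarity: recursive branch decomposition
(a node splits when both children reach the floor
`min_module_size * (1 - deep_split/6)`; nodes above the detection cut
height always split), followed by kME pruning (members below 0.3 own-kME
leave; modules shrinking below the size floor dissolve), kME adoption of
unassigned genes (≥0.3), and iterative merging of modules whose eigengene
dissimilarity is below the merge cut. This is validated by planted-module
recovery (ARI ≈ 0.99 at 2,000 genes / 120 samples / 20 resampled
networks) rather than label-exact equality with any particular published
implementation. Desk-scale defaults (min module size 30, 20 resamples)
scale down the full-scale profile (160 / deep split 4 / cut heights
0.9999 and 0.1 / 100 resamples) available via `NetworkParams.paper_scale()`.

Eigengenes are first principal components of the standardized module
submatrix, oriented so the mean own-module kME is positive. Module–trait
association regresses each eigengene on form (control baseline) and on
diagnosis, reporting `sign(sum of coefficients) * sqrt(max(adj R^2, 0))`
by default (a flag switches to signed adjusted R² itself; downstream code
treats it as descriptive only). Trajectories use a quadratic B-spline
basis with df = 2 and an interaction F-test per form vs control. The
preservation statistic averages a density Z (mean within-module adjacency
vs size-matched permutation null) and a connectivity Z (correlation of
reference intramodular connectivity with the candidate set's test
connectivity, against the same null).

## Regulation scores

`score(U -> V) = sum_{g in V, g targeted from U} kME_V(g) / |V|`, with
targets counted once regardless of regulator multiplicity and negative
kME entering as-is. Edges require `score > mean + 1 * population SD` over
all ordered pairs U ≠ V (both conventions configurable; the threshold is
computed per network). On default synthetic cohorts the threshold lands
near 0.29 with planted edges near 0.8, and recovery is exact with
truth annotations.

## Enrichment, deconvolution, PPI, CRISPRi

Fisher tests are two-sided by the minimum-likelihood rule; the reported
odds ratio is the sample OR with Haldane's 0.5 correction when a cell is
zero. The EWCE-style bootstrap uses per-gene specificity (expression
share across cell types), same-size random background sets and the
add-one p rule, BH across types.

Deconvolution builds per-type mean-CPM signatures restricted to top-
specificity markers and solves per-sample NNLS with rows scaled by the
inverse signature mean — expression noise is approximately multiplicative,
and without the scaling high-expression markers dominate the squared
loss — then renormalizes onto the simplex. Proportion tests use the
adjusted logit (`p* = a + (1-2a)p`, a = 0.001) and the same mixed-model
contrast machinery as expression.

PPI connectedness is the mean logFC over bait × member cells (zeros kept
for undetected pairs, bait self-entries excluded). The permutation null
draws size-matched sets from the detected universe excluding the tested
set and the baits, per the published procedure. Excluding the tested set
makes the null mean anti-correlated with the observed statistic and
inflates var(z) by `(N/(N-k))^2` (~10 % at k = 15, N = 295); a
`exclude_tested=False` flag gives an exactly calibrated null and is what
the calibration checks use, while power analyses keep the faithful
default.

CROP-seq assignment applies the UMI ≥ 10 threshold per guide, collapses
guides to their target, and assigns a cell only when exactly one target
passes (guide-level uniqueness behind a flag). Pseudobulk DE sums counts
per (arm, replicate) and applies a moderated two-sample t-test on log2
CPM with an empirical-Bayes variance squeeze (method-of-moments fit of a
scaled inverse-chi-square prior on log s², trigamma inverted by Newton
iteration) — a deliberate, calibration-validated replacement for a
quasi-likelihood F-test.

## Problem sizes and determinism

Default cohorts are 5,000 genes (chance correlation between planted
effect vectors scales as 1/sqrt(G); below ~2,000 genes it rivals the
day-25→50 convergence gap, while real analyses use ~20k expressed genes).
Network analyses run on 2,000 genes (the pipeline takes the most-variable
2,000 by default, standard practice for co-expression networks).
Recovery suites use 20 seeds in the tests and 5 in the acceptance script.
Every stochastic component takes an explicit seed; fixed seeds reproduce
outputs byte-for-byte.

## Known limitations

- One random intercept per gene (not the crossed individual/line/
  differentiation/resequencing structure); the nesting columns are
  retained so the grouping can be swapped.
- The residual-df Wald approximation is anti-conservative for severely
  unbalanced groupings; calibration is verified only at the simulated
  designs.
- The hybrid tree cut is a simplification; on data with weak or
  overlapping modules it will not match full dynamic-tree-cut output.
- Deconvolution assumes the reference spans the bulk mixture; no
  platform-effect correction is attempted.
- AU values come from the two-parameter fit only, with no higher-order
  refinement; clusters never observed at any scale get no AU.
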