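# Methods

## The screening model

The pipeline operationalizes the competing-endogenous-RNA (ceRNA)
hypothesis for two-group bulk transcriptomics. A lncRNA and an mRNA that
share miRNA response elements compete for the same miRNA pool, so their
transcript levels should be *positively* correlated; a lncRNA acquires
"immune-related" status transitively, by strong co-expression with an
immune-annotated mRNA (immune gene lists such as ImmPort's contain only
mRNAs). The admission rule for a pair is therefore a conjunction:

1. shared miRNA: `{m : (m, lnc) ∈ E ∧ (m, mRNA) ∈ E} ≠ ∅` over the
   bipartite interaction edge set `E`;
2. co-expression: Pearson `r > 0.8` across pooled samples, computed on the
   log2 scale; an optional high-stringency tier retains `|r| > 0.91`.

Positivity is the binding constraint: an anti-correlated pair is never a
ceRNA pair, however large `|r|`, because competition predicts
co-expression. Strongly negative pairs are still reported in the
correlation output, mirroring how published high-stringency tables list
them without admitting them to the final network.

### Differential expression

The DEG screen is the standard microarray recipe: Welch's unequal-variance
*t* on log2 expression (Kruskal–Wallis offered as the rank-based
alternative), `log2FC = mean(case) − mean(control)`, and the double cutoff
`p < α` (default 0.05, raw *p*) with `|log2FC| > 1`, strict at both
boundaries. Benjamini–Hochberg adjusted *p*-values are always computed and
can be used for the call (`use_adjusted=True`); raw *p* is the default
because fold-change double-filtering already controls the empirical false
positive rate at these settings (measured ≤ 0.07 on the synthetic null
genes) and matches common practice for this analysis style. Genes constant
in both groups get `p = 1` with a warning rather than an error. Linear-scale
input is transformed as `log2(x + 1)`.

### Correlation and its p-value

Pearson `r` is the product-moment estimator; its two-sided *p* comes from
`t = r sqrt((n−2)/(1−r²))` on `n−2` degrees of freedom. Correlations are
computed on pooled samples (both groups together) by default, matching how
published pair scatter plots pool control and case samples; a per-group
option exists. Pooling matters: for two genes both shifted by Δ in cases,
the group shift alone contributes `Δ²·v` to the covariance
(`v = p(1−p)` the case-fraction variance), so pooled `r` exceeds the
within-group correlation. This is a property of the analysis style, not of
this implementation; the synthetic decoys are designed around it (below).
Zero-variance genes yield records flagged `degenerate` (r set to 0) and
are excluded from admission. Correlation *p* is reported but not used for
admission by default; `corr_alpha` adds it as a requirement.

### Cross-cohort validation

The retention rule is the strictest reading of dataset-level validation:
both members significantly DE in the expected direction (default "up in
cases", the direction biomarker pairs of this kind show; a
direction-agnostic mode accepts any consistent direction) *and* a
significant positive correlation, all at the same α (default 0.05). No
fold-change cutoff is applied at validation — the discovery claim being
retested is direction + significance + co-expression, not effect size.

### Deconvolution

`estimate_fractions` re-implements the published support-vector
deconvolution scheme: per sample, regress the marker-gene profile on the
signature matrix with linear ν-SVR over ν ∈ {0.25, 0.5, 0.75}, keep the
lowest-RMSE fit, clamp negative coefficients to zero, renormalize to sum
to 1. For the ν-SVR path the sample profile is z-scored and the signature
standardized by its global mean/sd, as in the original algorithm. NNLS on
the untransformed linear scale is the default method: it is an order of
magnitude faster and on noise-free mixtures inverts the linear mixing
exactly (recovery to machine precision), which the SVR path's
standardization deliberately trades away for robustness. The per-sample
empirical *p* is `(1 + #{permutations with reconstruction correlation ≥
observed}) / (n_perm + 1)`, permuting the sample's marker values; the
`p < 0.05` sample filter is exposed via `significant_samples`. Log2-scale
input is de-logged as `2^x − 1` (clipped at 0), inverting the package's own
log transform.

Group comparison of fractions uses the Kruskal–Wallis rank test by default
(for two groups this is the rank-sum test) or the two-sample Wilcoxon
rank-sum (Mann–Whitney U), with BH adjustment across cell types.

## The synthetic-data generator

The generator emulates the study conditions the pipeline targets: an
11-control / 15-case cohort (validation replicates default to 11 vs 12),
~1,000 genes of which ~100 are lncRNAs, log2-normal baselines
(mean 6, between-gene sd 2), within-group noise sd 0.5, planted
|log2FC| = 2 on 60 background DEGs, 10 planted pairs at target r = 0.95,
and 10 decoys per class — sized so a full pipeline run takes seconds.

**Latent-factor pairs.** A planted pair's members are
`sqrt(|r|)·σ·f + sqrt(1−|r|)·σ·ε` around their baselines, with a shared
standard-normal factor `f` and independent `ε`; every gene keeps total
within-group sd σ and the within-group correlation is exactly the target
(the closed form `r = λ²/(λ²+σ²)` with `λ² = |r|σ²`). `r = 1` with σ > 0
is rejected as infeasible. `resample()` redraws a cohort of any size from
the same planted structure, which is how validation cohorts are made.

**Decoy classes** each violate exactly one admission criterion and are
verifiable from the emitted tables alone:

* *correlated-no-miRNA* — latent factor as for planted pairs, but the
  members share no miRNA (background edge generation explicitly avoids
  creating a shared miRNA for them);
* *miRNA-no-correlation* — shared miRNAs, independent noise;
* *anti-correlated* — shared miRNAs, factor loadings of opposite sign.

Fold-change direction interacts with pooled correlation (see above): with
both members shifted +2, even an independent decoy would show pooled
r ≈ Δ²v/(σ²+Δ²v) ≈ 0.8 purely from the group shift. Planted pairs and
correlated-no-miRNA decoys are both shifted up (matching the all-up
published pairs, and only raising their pooled r); the uncorrelated and
anti-correlated classes get opposite-direction shifts (lncRNA up, mRNA
down), so each decoy is rejected at the gate it is designed to probe
rather than slipping through on shift-induced correlation. This is a
deliberate generator design choice, documented here because a generator
with all-up decoys would mostly be testing that confounder instead.

**Mixtures.** The bundled synthetic signature has 5 cell types × 12
markers each, log-normal baselines (~20 units) with an 8-fold block boost
for each type's own markers. Fractions are symmetric-Dirichlet
(concentration 1, i.e. uniform on the simplex) unless supplied; mixtures
are `S·f` plus linear-scale Gaussian noise (default sd 5, a few percent of
signal) truncated at zero. Noise is Gaussian on the log2 scale for the
transcriptome (correlation analysis lives there) and on the linear scale
for mixtures (signature regression lives there).

**What the generator does not emulate:** probe-level microarray effects,
batch/platform differences, count noise (no negative-binomial layer),
miRNA expression itself, and correlated immune-cell co-variation. Passing
recovery tests therefore demonstrate that the implementation recovers its
stated model — not that the thresholds are well-calibrated for any
particular real cohort.

## Numerical and design choices

* Duplicate gene rows (multi-probe symbols) collapse by per-sample max
  (mean selectable). Symbol matching is exact; an uppercase-normalization
  flag exists for human symbols.
* TSV dialect: tabs, `.` decimal, no quoting, UTF-8; typographic minus
  (U+2212) normalized to ASCII on read so printed journal tables load
  verbatim.
* Expression containers may be ungrouped (`groups=None`) — signature
  mixtures have no case/control structure; operations that need groups
  raise. Grouped matrices require ≥ 2 samples per group.
* Pair admission ties are broken lexicographically by (lncRNA, mRNA) after
  sorting by r descending, so outputs are reproducible.
* The high-stringency tier is applied after the miRNA join; the two
  filters commute, so the order does not affect the final set.
* All generators take integer seeds through `numpy.random.default_rng`;
  identical seeds give bit-identical outputs.
* Problem sizes in the test and acceptance suites (≈1,000-gene cohorts,
  five seed replicates, 2,000-sample convergence checks, 4,000-gene null
  calibration, 50 mixtures) were chosen so the whole suite runs in seconds
  while keeping Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* The two-group test is gene-wise Welch/Kruskal; no moderated variance
  (limma-style) or count model, so very small cohorts with heavy-tailed
  noise will be under-powered relative to specialized tools.
* Pooled correlation conflates within-group co-regulation with shared
  differential expression; the per-group option exists but the default
  mirrors the published analysis style.
* Deconvolution assumes the signature's linear mixing on the linear
  scale; it does not implement absolute-mode scoring or signature
  construction from single-cell data.
* The interaction table is taken as given; no sequence-based miRNA target
  prediction is performed.
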