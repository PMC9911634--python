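# Methods

## Problem setting

Hepatocellular carcinoma (HCC) tumors stratify into an *inflamed* class —
high immune infiltration and cytolytic activity, better response to immune
checkpoint blockade — and a *non-inflamed* class. In practice the class is
called from a single biopsy, but HCC shows substantial intra-tumor
heterogeneity (ITH): spatially distinct regions of one tumor can differ
markedly at the transcriptome level, so a signature built from genes whose
expression varies between regions can classify the same tumor differently
depending on where the needle landed. This package implements a derivation
pipeline that filters signature genes on a gene-wise ITH statistic, so that
the resulting immune signature scores a tumor nearly identically regardless
of the region sampled, together with the concordance statistics needed to
demonstrate that property on multi-region cohorts.

## Integrated heterogeneity score (IHS)

For each gene, multi-region data (patients $p = 1..P$, regions $r$ within
patient) yield two complementary heterogeneity components:

* **Within-tumor variance share** $H_1 = 1 - \mathrm{ICC}$, where ICC is the
  one-way random-effects intraclass correlation with patients as groups:
  $\mathrm{MSB} = \sum_p n_p(\bar x_p - \bar x)^2/(P-1)$,
  $\mathrm{MSW} = \sum_{p,r}(x_{pr} - \bar x_p)^2/(N-P)$,
  $k_0 = (N - \sum_p n_p^2/N)/(P-1)$, and
  $\mathrm{ICC} = (\mathrm{MSB}-\mathrm{MSW})/(\mathrm{MSB}+(k_0-1)\mathrm{MSW})$,
  clipped to $[0,1]$. A gene constant across all used samples gets ICC = 1
  (flagged): identical everywhere is maximally clonal, and the convention
  avoids 0/0.
* **Subclonal event frequency** $E$: the fraction of patients whose
  within-tumor range $\max_r x_{pr} - \min_r x_{pr}$ exceeds $\tau$
  (default 1 log2 unit, a two-fold swing).

Both components are mapped to ascending percentile ranks across retained
genes (average ties, scaled to $(0,1]$ by rank/$G$, so the mean rank is
exactly $(G+1)/2G$), and IHS is the mean of the two ranks. Rank integration
makes the composite scale-free and robust to the very different sampling
distributions of a variance ratio and a threshold frequency. Low IHS means
clonal, representative expression. The composition of the score out of these
two particular components is this package's own documented construction of
a gene-wise ITH index with the stated properties; both components and both
ranks are exported so users can re-weight or substitute.

Practical conventions: genes with mean expression below 1.0 (log2 scale) are
excluded before ranking because variance ratios of near-silent genes are
noise-dominated; patients contributing a single region are excluded (a
single region carries no within-tumor information); ranks tie-break is
average, and gene selection tie-breaks are by smaller $H_1$, then gene id,
so every output is fully deterministic.

## Immune module by NMF

The non-negative expression matrix $V$ (genes × samples, log2(x+1)) is
factorized as $V \approx WH$ at rank $k$ by multiplicative updates for the
Frobenius objective:

$$W \leftarrow W \odot \frac{VH^\top}{WHH^\top + \delta},\qquad
  H \leftarrow H \odot \frac{W^\top V}{W^\top W H + \delta},\qquad
  \delta = 10^{-12}.$$

Initial entries are Uniform$(0, \sqrt{\overline V / k})$ from a seeded
generator, one independent stream per restart; optimization stops when the
relative per-iteration loss decrease falls below `nmf_tol` or at
`nmf_max_iter`, and the restart with the smallest final loss is kept.
Multiplicative updates never increase the objective, so the loss trajectory
is monotone — this is asserted in tests rather than assumed.

The *immune* factor is the row of $H$ whose per-sample weights correlate
best (Pearson) with a marker score: the mean cohort z-score of a marker
panel. On human data the default panel is CD8A, CD8B, GZMA, GZMB, PRF1,
IFNG, CXCL9, CXCL10, CD274, CTLA4 (cytotoxic effectors, IFN-γ axis,
checkpoints); simulated cohorts pass a subset of their planted immune genes.
Zero-variance $H$ rows are never selected. The immune-related gene set is
the `n_top_loading` genes (default 500) with the largest loadings on that
factor.

Defaults that are genuinely open choices: rank $k=6$ (small enough to fit a
desk-scale cohort, large enough to separate one immune module from patient
and background structure), 5 restarts, 500 iterations, tol $10^{-5}$, no
variance pre-selection of genes. All are config-exposed.

## Signature derivation, scoring, classification, concordance

The ITH-robust signature is the intersection of the top-loading immune
module genes with the `n_low_ihs` (default 2000) lowest-IHS genes. An empty
intersection is a warning, not an error; scoring then fails fast.

A sample's signature score is the mean over signature genes of the gene's
cohort z-score (population sd; zero-variance genes dropped with a warning;
at least half the signature must be present in the matrix). Samples are
labeled *inflamed* iff their score reaches the empirical `class_quantile`
(default 2/3, linear interpolation between order statistics): the top
tertile of samples is inflamed. Scoring and the cutpoint are deliberately
cohort-relative, making classification scale-free; the two-class reading of
the tertile rule (top tertile vs rest) is a documented choice, and the
quantile is exposed for sensitivity analysis.

A patient with $\geq 2$ classified regional samples is *concordant* when all
regions share one label and *discordant* otherwise; the cohort discordance
rate is the fraction of eligible patients that are discordant. Uncertainty
is a percentile bootstrap over eligible patients (default 1000 resamples,
seeded). Two signatures evaluated on the same patients are compared by the
paired rate difference with a patient-level paired bootstrap CI and an exact
sign test (binomial, p = 0.5) over patients whose concordance flags
disagree.

## Synthetic cohorts

The generator emulates exactly the structure the analysis must disentangle,
per gene $g$, patient $p$, region $r$, all on the log2 scale and clipped at
zero:

$$x_{g,(p,r)} = \mu_0 + a_{g,p} + \mathrm{effect}_{g,(p,r)} + \varepsilon,
\qquad a_{g,p}\sim N(0,\sigma_a),\ \varepsilon\sim N(0,\sigma_e)$$

with a latent immune level $\theta_p \sim U(0,1)$ per patient and per-region
jittered copies $\theta_{p,r} = \mathrm{clip}_{[0,1]}(\theta_p + N(0, s))$
drawn once per region and shared by all genes of a category ($s = 0.05$ for
the clonal program, $0.35$ for the subclonal one). Gene categories:
*clonal-immune* (effect $\beta\,\theta^{cl}_{p,r}$), *subclonal-immune*
(effect $\beta\,\theta^{sub}_{p,r}$), *subclonal background* (independent
$N(0,\sigma_s)$ per region), *stable background* ($N(0,\sigma_r)$ per
region). Defaults: 20 patients × 4 regions, 3000 genes with 150/150/300
special genes, $\mu_0=3$, $\sigma_a=0.8$, $\sigma_r=0.15$, $\sigma_s=1.2$,
$\beta=2$, $\sigma_e=0.3$. A patient is truly inflamed when $\theta_p$
reaches the cohort's upper tertile.

The gene-by-patient effect $a_{g,p}$ is essential — without it there is no
between-patient variance and the ICC degenerates — and the zero-clip mimics
the log2(x+1) floor while keeping the matrix valid NMF input. What the
generator does **not** emulate: count-level sampling noise and library-size
effects, tumor purity, copy-number-driven expression, correlated background
programs shared between patients, and realistic gene-gene correlation
beyond the planted modules. Passing tests therefore demonstrate that the
statistical machinery recovers planted structure under this hierarchy of
variance components — not that any particular gene list generalizes to real
tumors.

## Recovery behaviour and a known limitation

Two regimes matter for interpreting the simulation results:

* The IHS stage is reliable at the default conditions: clonal-immune genes
  get the lowest mean IHS of all categories, and roughly 80% of them land in
  the lowest-1000 set out of 3000 genes.
* The NMF stage is the bottleneck. The unstructured $a_{g,p}$ field carries
  roughly twenty times the squared-Frobenius mass of the planted immune
  module (3000 genes × variance 0.64 vs 300 genes × ≈0.33), so at rank 6 the
  immune factor absorbs background genes whose patient effects spuriously
  track $\theta$ across only 20 patients. In consequence the derived
  signature's precision for planted clonal-immune genes at the default
  conditions is typically ~0.7 (range ≈0.5–0.9 across seeds), and does not
  stably exceed 0.8. This is not an optimization artifact: extending the
  iteration budget 4–10× leaves precision essentially unchanged, and an
  independent NNDSVD-initialized coordinate-descent factorization
  (scikit-learn) improves it only moderately. It is a
  signal-to-background property of the design: more patients, a milder
  $\sigma_a$, or a larger planted module all restore precision ≥ 0.8 (the
  test suite demonstrates this on cohorts with $\sigma_a = 0.2$). The
  discordance ordering — the pipeline's central claim — is unaffected:
  clonal-immune signatures classify multi-region tumors strictly more
  concordantly than subclonal ones in 20/20 evaluation cohorts, and the
  residual stable-background genes that do enter the signature are
  themselves clonally expressed, which preserves concordance and keeps the
  score tightly correlated (r ≈ 0.97) with the pure planted immune score.

## Numerical and reproducibility choices

* All randomness flows from integer seeds through `numpy` `SeedSequence`
  streams; the pipeline's single config seed fans out to per-stage streams
  (simulate, NMF, bootstrap) so stages are independently reproducible.
  Re-running a pipeline config reproduces byte-identical TSV/JSON outputs.
* Expression scale is a user contract (log2(x+1) expected); the package
  never re-transforms silently. Missing values are rejected at load, and
  duplicate gene rows collapse by mean with a logged warning.
* Quantiles use linear interpolation between order statistics; ranks use
  average ties; all selection tie-breaks end lexicographically on gene id.
* Degenerate inputs have documented conventions: constant genes (ICC = 1,
  flagged), constant score vectors (all samples inflamed, warning),
  zero-variance marker/signature genes (dropped, warning), zero-variance
  $H$ rows (never selected).
* Problem sizes in tests and evaluation scripts: the reference design
  (20 × 4, 3000 genes) for the acceptance-level experiments; smaller cohorts
  (≈600 genes, 15 × 4) for module-level recovery tests, chosen so the
  recovery properties under test are stable across seeds.

## Scope

The package operates downstream of normalized expression: no FASTQ/BAM
processing, no count normalization or batch correction, no survival or
immunotherapy-response analysis, no ontology-based functional similarity,
no clonal phylogeny or purity modelling. Rank selection for NMF (consensus /
cophenetic surveys) is deliberately out of scope; the rank is a config
parameter.
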