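# ithsig — ITH-aware immune signatures for multi-region tumor RNA-seq

Calling a tumor *inflamed* (immune-infiltrated, likely to respond to immune
checkpoint blockade) or *non-inflamed* from a single biopsy is unreliable
when the genes in the classifier vary between regions of the same tumor.
`ithsig` implements a derivation pipeline for hepatocellular carcinoma-style
bulk RNA-seq that makes the classification robust to intra-tumor
heterogeneity (ITH), plus the statistics to prove it on multi-region
cohorts:

1. **IHS** — a gene-wise *integrated heterogeneity score*: the rank-average
   of the within-tumor variance share $H_1 = 1-\mathrm{ICC}$ (one-way
   random-effects intraclass correlation, patients as groups) and the
   frequency $E$ of within-tumor expression swings larger than τ = 1 log2
   unit. Low IHS = clonal, representative expression.
2. **Immune module** — rank-k NMF ($V \approx WH$, multiplicative updates,
   Frobenius loss, seeded restarts); the factor whose sample weights best
   correlate with an immune marker score is the immune module, and its
   top-loading genes are the immune-related gene set.
3. **Signature** — the intersection of the immune-module genes with the
   lowest-IHS genes. Samples are scored by mean cohort z-score over the
   signature and classified inflamed / non-inflamed at the upper tertile.
4. **Concordance** — a multi-region tumor is *concordant* when all its
   regions get the same label; the cohort discordance rate (with
   patient-level bootstrap CIs and paired signature comparisons) quantifies
   robustness to sampling location.

A fully seeded synthetic-cohort generator plants patient baselines, clonal
and subclonal immune programs, subclonal background and noise, so every
stage is testable against known ground truth without external data. It is
aimed at computational biologists working with multi-region bulk expression
who need ITH-robust classifiers or the concordance statistics to audit an
existing one.

## Worked example

The numbered scripts under `analysis/` run the whole study on the reference
synthetic cohort (20 patients × 4 regions, 3000 genes, 150 clonal-immune +
150 subclonal-immune + 300 subclonal-background genes):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_gene_heterogeneity.py
python analysis/03_immune_module.py
python analysis/04_derive_signature.py
python analysis/05_concordance.py
```

which prints, among other things:

```text
mean heterogeneity components by true gene category:
                         h1  event_freq    ihs
clonal_immune         0.098       0.112  0.232
stable_background     0.161       0.148  0.438
subclonal_immune      0.324       0.577  0.861
subclonal_background  0.718       0.944  0.950

signature: 139 genes (300 immune-module genes ∩ 1000 low-IHS genes)
clonal-immune recovery: precision 0.71, recall 0.66 (99/150 planted genes)

derived signature on the reference cohort: discordance 15.0% (3/20 patients)
score correlation with planted clonal-immune signature: r = 0.97 (Spearman 0.96)

clonal vs subclonal immune signature over 20 evaluation cohorts:
  mean discordance 12.8% vs 60.8%; clonal strictly lower in 20/20 cohorts
```

Reading this: genes carrying the immune program clonally get by far the
lowest heterogeneity scores, so the IHS filter keeps them and rejects the
subclonally expressed immune genes; the derived signature is dominated by
clonal-immune genes; and a clonally expressed signature classifies
multi-region tumors far more concordantly (≈13% of patients discordant)
than a subclonal one (≈61%) while still measuring the same immune axis
(r ≈ 0.97). See `docs/methods.md` for the model, conventions, and known
limitations — in particular why signature precision saturates around 0.7–0.8
under the reference noise conditions.

The same pipeline runs on real data from the standard formats (expression
TSV, annotation TSV, GMT), either via the library or the CLI:

```bash
ith-sig run --config run.yaml          # end-to-end with a manifest
ith-sig ihs --expr expr.tsv --annot annot.tsv --out ihs.tsv
ith-sig score --expr expr.tsv --signature sig.gmt --out scores.tsv
ith-sig classify --scores scores.tsv --out classes.tsv
ith-sig concordance --classes classes.tsv --annot annot.tsv --out report.json
```

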