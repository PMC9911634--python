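"""Signature derivation, sample scoring, and tertile classification.

The ITH-robust inflamed signature is the intersection of (a) the top-loading
genes of the NMF immune module and (b) the lowest-IHS (most clonally
expressed) genes. A sample's signature score is the mean cohort z-score over
the signature's genes; samples are split into *inflamed* and *non-inflamed*
at an empirical score quantile (default 2/3: the top tertile is inflamed).
Scores and cutpoints are cohort-relative by design — classification is
scale-free within each analyzed cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSet, ValidationError
from .nmf import zscore_genes

logger = logging.getLogger("ithsig")

INFLAMED, NON_INFLAMED = "inflamed", "non_inflamed"


@dataclass(frozen=True)
class SignatureGeneSet(GeneSet):
    """Gene set with derivation provenance: per-gene loading and IHS ranks."""

    loading_rank: dict | None = None  # gene -> 1-based rank among top loadings
    ihs_rank: dict | None = None  # gene -> 1-based rank among low-IHS genes
    config_snapshot: dict | None = None

    def __post_init__(self) -> None:  # empty intersection is legal here
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} has duplicate genes")


@dataclass(frozen=True)
class ClassificationResult:
    scores: pd.Series  # per-sample signature score
    cutpoint: float
    labels: pd.Series  # per-sample label in {inflamed, non_inflamed}
    class_quantile: float


def derive_signature(
    top_loading: GeneSet,
    low_ihs: GeneSet,
    config_snapshot: dict | None = None,
    name: str = "ith_robust_signature",
) -> SignatureGeneSet:
    """Intersect immune-module genes with clonally expressed (low-IHS) genes.

    An empty intersection is returned as an empty signature with a prominent
    warning rather than an error; downstream scoring then fails fast.
    """
    if len(top_loading) == 0 or len(low_ihs) == 0:
        raise ValidationError("both input gene sets must be non-empty")
    low_set = set(low_ihs.genes)
    genes = tuple(g for g in top_loading.genes if g in low_set)
    if not genes:
        logger.warning(
            "EMPTY SIGNATURE: no overlap between %d immune-module genes and "
            "%d low-IHS genes", len(top_loading), len(low_ihs),
        )
    loading_rank = {g: i + 1 for i, g in enumerate(top_loading.genes) if g in genes}
    ihs_rank = {g: i + 1 for i, g in enumerate(low_ihs.genes) if g in genes}
    return SignatureGeneSet(
        name=name,
        description=(
            f"intersection of {len(top_loading)} immune-module genes "
            f"with {len(low_ihs)} low-IHS genes ({len(genes)} genes)"
        ),
        genes=genes,
        loading_rank=loading_rank,
        ihs_rank=ihs_rank,
        config_snapshot=config_snapshot,
    )


def score_samples(expr: ExpressionMatrix, signature: GeneSet) -> pd.Series:
    """Per-sample signature score: mean cohort z-score over signature genes.

    Requires at least half the signature's genes in the matrix; missing genes
    are logged, zero-variance genes are dropped with a warning.
    """
    if len(signature.genes) == 0:
        raise ValidationError("cannot score an empty signature")
    present = [g for g in signature.genes if g in expr.data.index]
    missing = [g for g in signature.genes if g not in expr.data.index]
    if len(present) < 0.5 * len(signature.genes):
        raise ValidationError(
            f"only {len(present)}/{len(signature.genes)} signature genes present; "
            f"missing: {missing}"
        )
    if missing:
        logger.warning("signature genes absent from matrix: %s", missing)
    z = zscore_genes(expr, present)
    scores = z.mean(axis=0)
    scores.name = signature.name
    return scores


def classify_tertile(
    scores: pd.Series, class_quantile: float = 2.0 / 3.0
) -> ClassificationResult:
    """Label samples inflamed iff score >= the empirical quantile cutpoint.

    The cutpoint uses linear interpolation between order statistics; with the
    default quantile 2/3 and distinct scores the top third is inflamed. A
    degenerate (constant) score vector labels every sample inflamed, with a
    warning.
    """
    if not (0.0 < class_quantile < 1.0):
        raise ValidationError("class_quantile must lie strictly in (0, 1)")
    if len(scores) < 3:
        raise ValidationError("need at least 3 samples to classify")
    cut = float(np.quantile(scores.to_numpy(), class_quantile, method="linear"))
    if scores.nunique() == 1:
        logger.warning("degenerate score distribution: all samples inflamed")
    labels = pd.Series(
        np.where(scores.to_numpy() >= cut, INFLAMED, NON_INFLAMED),
        index=scores.index,
        name="label",
    )
    return ClassificationResult(
        scores=scores, cutpoint=cut, labels=labels, class_quantile=class_quantile
    )


def signature_correlation(scores_a: pd.Series, scores_b: pd.Series) -> dict:
    """Pearson and Spearman correlation of two signatures' sample scores."""
    if len(scores_a) != len(scores_b) or len(scores_a) < 3:
        raise ValidationError("score vectors must have equal length >= 3")
    b = scores_b.reindex(scores_a.index)
    if b.isna().any():
        raise ValidationError("sample ids of the two score vectors do not match")
    a_v, b_v = scores_a.to_numpy(), b.to_numpy()
    if np.std(a_v) == 0 or np.std(b_v) == 0:
        raise ValidationError("zero variance in a score vector")
    pearson = stats.pearsonr(a_v, b_v)
    spearman = stats.spearmanr(a_v, b_v)
    return {
        "pearson_r": float(pearson.statistic),
        "pearson_p": float(pearson.pvalue),
        "spearman_rho": float(spearman.statistic),
        "spearman_p": float(spearman.pvalue),
        "n": len(scores_a),
    }
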