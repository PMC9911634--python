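"""Gene-wise integrated heterogeneity score (IHS) from multi-region expression.

A gene expressed *clonally* within tumors looks the same in every region of a
patient's tumor, so a single biopsy represents the whole tumor for that gene.
IHS quantifies the opposite — intra-tumor expression heterogeneity — by
integrating two complementary per-gene components:

* ``H1 = 1 - ICC``: the share of a gene's variance that is *within* patients,
  from the one-way random-effects intraclass correlation (patients as groups,
  regions as replicates).
* ``E``: the subclonal *event frequency* — the fraction of patients whose
  within-tumor expression range exceeds a threshold ``tau`` (default 1 log2
  unit, i.e. a two-fold swing between regions).

Each component is converted to an ascending percentile rank across retained
genes (average ties, scaled to (0, 1]) and IHS is the mean of the two ranks.
Rank integration makes the score scale-free; low IHS = clonal, representative
expression. This composition is this package's declared construction of the
score — both components are exported so users can re-weight.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import (
    AnalysisConfig,
    ExpressionMatrix,
    GeneSet,
    SampleAnnotation,
    ValidationError,
)

logger = logging.getLogger("ithsig")

IHS_COLUMNS = (
    "h1", "event_freq", "rank_h1", "rank_e", "ihs",
    "n_patients_used", "flagged_constant",
)


def _check_groups(groups: Sequence[np.ndarray]) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("need at least 2 groups")
    for i, g in enumerate(arrays):
        if g.ndim != 1 or g.size < 2:
            raise ValidationError(f"group {i} has fewer than 2 values")
    return arrays


def icc_oneway(values_by_patient: Sequence[Sequence[float]]) -> float:
    """One-way random-effects ANOVA intraclass correlation, clipped to [0, 1].

    With P groups of sizes n_p (N total), group means m_p and grand mean m:

        MSB = sum n_p (m_p - m)^2 / (P - 1)
        MSW = sum_p sum_r (x_pr - m_p)^2 / (N - P)
        k0  = (N - sum n_p^2 / N) / (P - 1)
        ICC = (MSB - MSW) / (MSB + (k0 - 1) MSW)

    k0 is the unbalanced-design average group size. A constant gene
    (MSB = MSW = 0) returns ICC = 1: identical everywhere is maximally clonal.
    """
    groups = _check_groups(values_by_patient)
    sizes = np.array([g.size for g in groups], dtype=float)
    P, N = len(groups), sizes.sum()
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    msb = float(np.sum(sizes * (means - grand) ** 2) / (P - 1))
    msw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)) / (N - P))
    if msb == 0.0 and msw == 0.0:
        return 1.0
    k0 = (N - np.sum(sizes**2) / N) / (P - 1)
    icc = (msb - msw) / (msb + (k0 - 1.0) * msw)
    return float(np.clip(icc, 0.0, 1.0))


def event_frequency(
    values_by_patient: Sequence[Sequence[float]], tau: float
) -> float:
    """Fraction of patients whose within-tumor range exceeds tau (log2 units)."""
    if tau <= 0:
        raise ValidationError("tau must be > 0")
    groups = _check_groups(values_by_patient)
    events = sum(1 for g in groups if (g.max() - g.min()) > tau)
    return events / len(groups)


def _patient_column_groups(
    expr: ExpressionMatrix, annot: SampleAnnotation
) -> tuple[list[str], list[np.ndarray]]:
    """Column-index groups for patients with >= 2 profiled regions."""
    annot.check_matches(expr)
    col_of = {s: i for i, s in enumerate(expr.sample_ids)}
    patients, groups = [], []
    n_single = 0
    for pid, samples in annot.samples_by_patient().items():
        if len(samples) < 2:
            n_single += 1
            continue
        patients.append(pid)
        groups.append(np.array([col_of[s] for s in samples]))
    if n_single:
        logger.warning("excluded %d single-region patients from IHS", n_single)
    if len(patients) < 2:
        raise ValidationError("need >= 2 patients with >= 2 regions each")
    return patients, groups


def compute_ihs(
    expr: ExpressionMatrix,
    annot: SampleAnnotation,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-gene heterogeneity table (index gene_id, columns IHS_COLUMNS).

    Genes whose mean expression falls below ``expression_filter_min_mean``
    are excluded before ranking (variance ratios of near-silent genes are
    noise-dominated); patients with a single region are excluded. Fully
    deterministic given inputs.
    """
    config = config or AnalysisConfig()
    patients, groups = _patient_column_groups(expr, annot)
    P = len(patients)

    used_cols = np.concatenate(groups)
    X_all = expr.values
    keep = X_all.mean(axis=1) >= config.expression_filter_min_mean
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "expression filter (mean >= %g) dropped %d of %d genes",
            config.expression_filter_min_mean, n_dropped, keep.size,
        )
    if not keep.any():
        raise ValidationError("no genes pass the expression filter")
    genes = np.asarray(expr.gene_ids)[keep]
    X = X_all[keep]

    sizes = np.array([g.size for g in groups], dtype=float)
    N = sizes.sum()
    group_means = np.stack([X[:, g].mean(axis=1) for g in groups], axis=1)  # G x P
    grand = X[:, used_cols].mean(axis=1)
    ssb = np.einsum("p,gp->g", sizes, (group_means - grand[:, None]) ** 2)
    ssw = np.zeros(X.shape[0])
    ranges = np.zeros((X.shape[0], P))
    for p, g in enumerate(groups):
        block = X[:, g]
        ssw += ((block - group_means[:, p][:, None]) ** 2).sum(axis=1)
        ranges[:, p] = block.max(axis=1) - block.min(axis=1)
    msb = ssb / (P - 1)
    msw = ssw / (N - P)
    k0 = (N - np.sum(sizes**2) / N) / (P - 1)

    constant = (msb == 0.0) & (msw == 0.0)
    denom = msb + (k0 - 1.0) * msw
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = np.clip((msb - msw) / denom, 0.0, 1.0)
    icc[constant] = 1.0
    h1 = 1.0 - icc
    e = (ranges > config.event_threshold_tau).mean(axis=1)

    n_genes = genes.size
    rank_h1 = rankdata(h1, method="average") / n_genes
    rank_e = rankdata(e, method="average") / n_genes
    table = pd.DataFrame(
        {
            "h1": h1,
            "event_freq": e,
            "rank_h1": rank_h1,
            "rank_e": rank_e,
            "ihs": (rank_h1 + rank_e) / 2.0,
            "n_patients_used": P,
            "flagged_constant": constant,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return table


def select_low_ihs(table: pd.DataFrame, n: int) -> GeneSet:
    """The n genes with smallest IHS; ties broken by smaller H1, then gene id."""
    n_retained = len(table)
    if n > n_retained:
        raise ValidationError(
            f"requested {n} low-IHS genes but only {n_retained} retained"
        )
    order = table.assign(_gene=table.index).sort_values(
        ["ihs", "h1", "_gene"], kind="mergesort"
    )
    chosen = order.index[:n]
    return GeneSet(
        name=f"low_ihs_{n}",
        description=f"{n} lowest-IHS genes of {n_retained} retained",
        genes=tuple(chosen),
    )
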