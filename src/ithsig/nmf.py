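"""Immune-module discovery by non-negative matrix factorization.

The expression matrix V (genes x samples, non-negative) is factorized as
V ~ W H with W >= 0 (gene loadings) and H >= 0 (sample weights), minimizing
the Frobenius reconstruction error with Lee-Seung multiplicative updates:

    W <- W * (V H^T) / (W H H^T + delta)
    H <- H * (W^T V) / (W^T W H + delta),   delta = 1e-12

Multiplicative updates never increase the objective and preserve
non-negativity, so the loss trajectory is monotone by construction. The
factorization is restarted from several seeded random initializations and the
restart with the smallest final loss is kept — everything is deterministic
given the seed.

The *immune* factor is the one whose per-sample weights (row of H) correlate
best with a marker score: the mean cohort z-score of a panel of immune marker
genes (cytotoxic T-cell markers by default on human data; simulations pass a
subset of their planted immune genes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, ValidationError

logger = logging.getLogger("ithsig")

_DELTA = 1e-12


@dataclass(frozen=True)
class NMFResult:
    W: pd.DataFrame  # genes x rank, non-negative loadings
    H: pd.DataFrame  # rank x samples, non-negative weights
    loss: tuple[float, ...]  # final Frobenius loss per restart
    chosen_restart: int
    loss_trajectory: tuple[float, ...]  # per-iteration loss of chosen restart
    rank: int
    seed: int


@dataclass(frozen=True)
class ImmuneFactorSelection:
    factor_index: int
    correlation_per_factor: tuple[float, ...]
    marker_score: pd.Series  # per-sample


def _mu_nmf(
    V: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    G, S = V.shape
    if init is not None:
        W, H = init[0].copy(), init[1].copy()
    else:
        scale = np.sqrt(V.mean() / k)
        W = rng.uniform(0.0, scale, size=(G, k))
        H = rng.uniform(0.0, scale, size=(k, S))
    trajectory: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        W *= (V @ H.T) / (W @ (H @ H.T) + _DELTA)
        H *= (W.T @ V) / ((W.T @ W) @ H + _DELTA)
        loss = float(np.linalg.norm(V - W @ H))
        trajectory.append(loss)
        if prev < np.inf and prev > 0 and (prev - loss) / prev < tol:
            break
        prev = loss
    return W, H, trajectory


def nmf_factorize(
    expr: ExpressionMatrix,
    k: int,
    restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-5,
    seed: int = 0,
) -> NMFResult:
    """Best-of-``restarts`` multiplicative-update NMF of the expression matrix."""
    V = expr.values
    if (V < 0).any():
        raise ValidationError("NMF requires a non-negative matrix")
    if k >= min(V.shape):
        raise ValidationError(
            f"rank k={k} must be smaller than min(genes, samples)={min(V.shape)}"
        )
    if restarts < 1:
        raise ValidationError("restarts must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(restarts)
    best = None
    losses: list[float] = []
    for r, ss in enumerate(streams):
        W, H, traj = _mu_nmf(V, k, np.random.default_rng(ss), max_iter, tol)
        losses.append(traj[-1])
        if best is None or traj[-1] < best[3][-1]:
            best = (r, W, H, traj)
    chosen, W, H, traj = best
    logger.info(
        "NMF k=%d: chose restart %d of %d (loss %.6g)", k, chosen, restarts, traj[-1]
    )
    factors = [f"factor_{i}" for i in range(k)]
    return NMFResult(
        W=pd.DataFrame(W, index=expr.gene_ids, columns=factors),
        H=pd.DataFrame(H, index=factors, columns=expr.sample_ids),
        loss=tuple(losses),
        chosen_restart=chosen,
        loss_trajectory=tuple(traj),
        rank=k,
        seed=seed,
    )


def zscore_genes(expr: ExpressionMatrix, genes: list[str]) -> pd.DataFrame:
    """Cohort z-scores across samples for the given genes; sd=0 genes dropped."""
    sub = expr.data.loc[genes]
    sd = sub.std(axis=1, ddof=0)
    zero_var = sd == 0
    if zero_var.any():
        logger.warning(
            "skipping %d zero-variance genes in z-scoring: %s",
            int(zero_var.sum()), list(sub.index[zero_var])[:10],
        )
        sub, sd = sub.loc[~zero_var], sd[~zero_var]
    if sub.empty:
        raise ValidationError("all requested genes have zero variance")
    return sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)


def marker_score(expr: ExpressionMatrix, markers: list[str]) -> pd.Series:
    """Per-sample mean cohort z-score over the marker genes present."""
    present = [g for g in markers if g in expr.data.index]
    absent = [g for g in markers if g not in expr.data.index]
    if absent:
        logger.warning("markers absent from matrix: %s", absent)
    if not present:
        raise ValidationError("no marker gene present in the expression matrix")
    z = zscore_genes(expr, present)
    return z.mean(axis=0)


def select_immune_factor(nmf: NMFResult, score: pd.Series) -> ImmuneFactorSelection:
    """Pick the factor whose sample weights best correlate with the marker score."""
    if len(score) != nmf.H.shape[1]:
        raise ValidationError("marker score length must equal sample count")
    score = score.reindex(nmf.H.columns)
    if score.isna().any():
        raise ValidationError("marker score sample ids do not match NMF samples")
    s = score.to_numpy()
    if np.std(s) == 0:
        raise ValidationError("marker score has zero variance")
    corrs = []
    for i in range(nmf.rank):
        h = nmf.H.iloc[i].to_numpy()
        if np.std(h) == 0:
            logger.warning("H row %d has zero variance; never selected", i)
            corrs.append(-np.inf)
        else:
            corrs.append(float(np.corrcoef(h, s)[0, 1]))
    best = int(np.argmax(corrs))  # argmax takes the lowest index on ties
    logger.info("immune factor = %d (r = %.3f)", best, corrs[best])
    return ImmuneFactorSelection(
        factor_index=best,
        correlation_per_factor=tuple(corrs),
        marker_score=score,
    )


def top_loading_genes(nmf: NMFResult, factor: int, n: int) -> GeneSet:
    """The n genes with largest loading on a factor; ties broken by gene id."""
    if not (0 <= factor < nmf.rank):
        raise ValidationError(f"factor {factor} out of range for rank {nmf.rank}")
    if n > nmf.W.shape[0]:
        raise ValidationError(
            f"requested {n} genes but matrix has {nmf.W.shape[0]}"
        )
    loadings = nmf.W.iloc[:, factor]
    order = (
        pd.DataFrame({"loading": loadings, "_gene": loadings.index})
        .sort_values(["loading", "_gene"], ascending=[False, True], kind="mergesort")
    )
    return GeneSet(
        name=f"top_loading_{n}_factor{factor}",
        description=f"top {n} loadings on NMF factor {factor}",
        genes=tuple(order.index[:n]),
    )
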