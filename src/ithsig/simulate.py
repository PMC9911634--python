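"""Synthetic multi-region tumor expression cohorts with known ground truth.

The generator emulates the statistical structure that multi-region bulk
RNA-seq of solid tumors exposes: patient-level expression baselines, a latent
immune-infiltration level per patient that is expressed either *clonally*
(nearly identical across a tumor's regions) or *subclonally* (varying region
to region), subclonal background programs unrelated to immunity, and
measurement noise. Everything is generated on the log2(x+1) scale and clipped
at zero, so the output satisfies the non-negativity contract of the NMF stage.

Generative model, per gene g, patient p, region r:

    x_{g,(p,r)} = mu0 + a_{g,p} + effect_{g,(p,r)} + eps,
    a_{g,p} ~ N(0, sigma_a),   eps ~ N(0, sigma_e)

with the effect term depending on the gene's category:

    clonal_immune        beta * clip01(theta_p + N(0, clonal_jitter_sd))
    subclonal_immune     beta * clip01(theta_p + N(0, subclonal_jitter_sd))
    subclonal_background N(0, sigma_s)   per region
    stable_background    N(0, sigma_r)   per region

theta_p ~ Uniform(0, 1) is the patient's latent immune level; the jittered
copies theta_{p,r} are drawn once per region and shared by all genes of the
category, so immune genes co-vary the way a real infiltration program does.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, SampleAnnotation, ValidationError

GENE_CATEGORIES = (
    "clonal_immune",
    "subclonal_immune",
    "subclonal_background",
    "stable_background",
)


@dataclass(frozen=True)
class SimulationParams:
    """Cohort design and variance components of the generative model.

    Defaults describe the study conditions used throughout the package's own
    evaluations: 20 patients x 4 regions, 3000 genes of which 150 carry the
    immune program clonally, 150 subclonally, and 300 form subclonal
    background programs. Scales are log2 units.
    """

    n_patients: int = 20
    regions_per_patient: int | tuple[int, ...] = 4
    n_genes: int = 3000
    n_clonal_immune: int = 150
    n_subclonal_immune: int = 150
    n_subclonal_background: int = 300
    baseline_mean: float = 3.0
    patient_sd: float = 0.8
    region_sd_clonal: float = 0.15
    region_sd_subclonal: float = 1.2
    immune_effect: float = 2.0
    noise_sd: float = 0.3
    clonal_jitter_sd: float = 0.05
    subclonal_jitter_sd: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValidationError("need at least 2 patients")
        for n in self.regions_list():
            if n < 2:
                raise ValidationError("every patient needs at least 2 regions")
        n_special = (
            self.n_clonal_immune + self.n_subclonal_immune + self.n_subclonal_background
        )
        if n_special > self.n_genes:
            raise ValidationError(
                f"category counts ({n_special}) exceed n_genes ({self.n_genes})"
            )
        for name in (
            "patient_sd", "region_sd_clonal", "region_sd_subclonal",
            "noise_sd", "clonal_jitter_sd", "subclonal_jitter_sd",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def regions_list(self) -> tuple[int, ...]:
        if isinstance(self.regions_per_patient, int):
            return (self.regions_per_patient,) * self.n_patients
        regions = tuple(self.regions_per_patient)
        if len(regions) != self.n_patients:
            raise ValidationError(
                "regions_per_patient list length must equal n_patients"
            )
        return regions


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a simulated cohort.

    gene_category: per-gene label (one of GENE_CATEGORIES), indexed by gene id.
    patient_theta: latent immune level per patient, in [0, 1].
    region_theta_clonal / region_theta_subclonal: the jittered per-region
        immune drivers actually used for the two immune categories, indexed
        by sample id.
    true_class: per-patient inflamed indicator — theta_p at or above the
        cohort's upper-tertile theta.
    """

    gene_category: pd.Series
    patient_theta: pd.Series
    region_theta_clonal: pd.Series
    region_theta_subclonal: pd.Series
    true_class: pd.Series

    def genes_in_category(self, category: str) -> list[str]:
        if category not in GENE_CATEGORIES:
            raise ValidationError(f"unknown gene category {category!r}")
        return list(self.gene_category.index[self.gene_category == category])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_category": self.gene_category.to_dict(),
            "patient_theta": self.patient_theta.to_dict(),
            "region_theta_clonal": self.region_theta_clonal.to_dict(),
            "region_theta_subclonal": self.region_theta_subclonal.to_dict(),
            "true_class": {k: bool(v) for k, v in self.true_class.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            gene_category=pd.Series(payload["gene_category"]),
            patient_theta=pd.Series(payload["patient_theta"], dtype=float),
            region_theta_clonal=pd.Series(payload["region_theta_clonal"], dtype=float),
            region_theta_subclonal=pd.Series(
                payload["region_theta_subclonal"], dtype=float
            ),
            true_class=pd.Series(payload["true_class"], dtype=bool),
        )


def _clip01(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)


def simulate_cohort(
    params: SimulationParams,
) -> tuple[ExpressionMatrix, SampleAnnotation, SyntheticTruth]:
    """Draw one cohort from the generative model. Fully reproducible from seed."""
    rng = np.random.default_rng(params.seed)
    regions = params.regions_list()
    P, G = params.n_patients, params.n_genes
    N = int(sum(regions))

    patient_ids = [f"P{p + 1:02d}" for p in range(P)]
    sample_ids, sample_patient_idx, region_ids = [], [], []
    for p, n_r in enumerate(regions):
        for r in range(n_r):
            sample_ids.append(f"{patient_ids[p]}_R{r + 1}")
            region_ids.append(f"R{r + 1}")
            sample_patient_idx.append(p)
    sample_patient_idx = np.asarray(sample_patient_idx)

    gene_ids = [f"G{g + 1:05d}" for g in range(G)]
    categories = np.full(G, "stable_background", dtype=object)
    i0 = 0
    for cat, n_cat in (
        ("clonal_immune", params.n_clonal_immune),
        ("subclonal_immune", params.n_subclonal_immune),
        ("subclonal_background", params.n_subclonal_background),
    ):
        categories[i0 : i0 + n_cat] = cat
        i0 += n_cat

    theta_p = rng.uniform(0.0, 1.0, size=P)
    theta_clonal = _clip01(
        theta_p[sample_patient_idx] + rng.normal(0.0, params.clonal_jitter_sd, N)
    )
    theta_subclonal = _clip01(
        theta_p[sample_patient_idx] + rng.normal(0.0, params.subclonal_jitter_sd, N)
    )

    a_gp = rng.normal(0.0, params.patient_sd, size=(G, P))
    x = params.baseline_mean + a_gp[:, sample_patient_idx]

    is_cl = categories == "clonal_immune"
    is_sub = categories == "subclonal_immune"
    is_sbg = categories == "subclonal_background"
    is_stb = categories == "stable_background"
    x[is_cl] += params.immune_effect * theta_clonal[None, :]
    x[is_sub] += params.immune_effect * theta_subclonal[None, :]
    x[is_sbg] += rng.normal(0.0, params.region_sd_subclonal, size=(int(is_sbg.sum()), N))
    x[is_stb] += rng.normal(0.0, params.region_sd_clonal, size=(int(is_stb.sum()), N))
    x += rng.normal(0.0, params.noise_sd, size=(G, N))
    np.clip(x, 0.0, None, out=x)

    expr = ExpressionMatrix(pd.DataFrame(x, index=gene_ids, columns=sample_ids))
    annot = SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "patient_id": [patient_ids[p] for p in sample_patient_idx],
                "region_id": region_ids,
            }
        )
    )
    cut = float(np.quantile(theta_p, 2.0 / 3.0))
    truth = SyntheticTruth(
        gene_category=pd.Series(categories, index=gene_ids),
        patient_theta=pd.Series(theta_p, index=patient_ids),
        region_theta_clonal=pd.Series(theta_clonal, index=sample_ids),
        region_theta_subclonal=pd.Series(theta_subclonal, index=sample_ids),
        true_class=pd.Series(theta_p >= cut, index=patient_ids),
    )
    return expr, annot, truth


def truth_recovery_report(truth: SyntheticTruth, signature: GeneSet) -> dict:
    """Precision/recall of planted clonal-immune genes inside a derived signature."""
    if len(signature) == 0:
        raise ValidationError("cannot score an empty signature")
    unknown = set(signature.genes) - set(truth.gene_category.index)
    if unknown:
        raise ValidationError(f"signature genes not in simulation: {sorted(unknown)[:10]}")
    clonal = set(truth.genes_in_category("clonal_immune"))
    hits = sum(1 for g in signature.genes if g in clonal)
    return {
        "n_signature": len(signature),
        "n_clonal_immune": len(clonal),
        "n_hits": hits,
        "precision": hits / len(signature),
        "recall": hits / len(clonal) if clonal else float("nan"),
    }
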