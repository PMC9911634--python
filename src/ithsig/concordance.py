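"""Per-patient classification concordance across intra-tumor regions.

A multi-region tumor is *concordant* when all of its regional samples receive
the same class (inflamed or non-inflamed) and *discordant* when its regions
split across both classes. The cohort discordance rate — the fraction of
eligible patients (>= 2 classified samples) whose tumors are discordant — is
the headline robustness statistic: a signature built from clonally expressed
genes should classify a tumor the same way no matter which region was
sampled. Uncertainty comes from a patient-level percentile bootstrap.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleAnnotation, ValidationError

logger = logging.getLogger("ithsig")


@dataclass(frozen=True)
class ConcordanceReport:
    per_patient: pd.DataFrame  # index patient_id; n_regions, labels, concordant
    n_eligible: int
    n_discordant: int
    discordance_rate: float
    ci_low: float
    ci_high: float
    ci_level: float
    n_boot: int
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "per_patient": {
                pid: {
                    "n_regions": int(row["n_regions"]),
                    "labels": list(row["labels"]),
                    "concordant": bool(row["concordant"]),
                }
                for pid, row in self.per_patient.iterrows()
            },
            "n_eligible": self.n_eligible,
            "n_discordant": self.n_discordant,
            "discordance_rate": self.discordance_rate,
            "ci": [self.ci_low, self.ci_high],
            "ci_level": self.ci_level,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ConcordanceReport":
        p = json.loads(Path(path).read_text())
        per_patient = pd.DataFrame(
            {
                "n_regions": {k: v["n_regions"] for k, v in p["per_patient"].items()},
                "labels": {k: tuple(v["labels"]) for k, v in p["per_patient"].items()},
                "concordant": {k: v["concordant"] for k, v in p["per_patient"].items()},
            }
        )
        per_patient.index.name = "patient_id"
        return cls(
            per_patient=per_patient,
            n_eligible=p["n_eligible"],
            n_discordant=p["n_discordant"],
            discordance_rate=p["discordance_rate"],
            ci_low=p["ci"][0],
            ci_high=p["ci"][1],
            ci_level=p["ci_level"],
            n_boot=p["n_boot"],
            seed=p["seed"],
        )


def evaluate_concordance(
    labels: pd.Series,
    annot: SampleAnnotation,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> ConcordanceReport:
    """Flag each multi-region patient as concordant/discordant and bootstrap the rate.

    ``labels`` is a per-sample class label Series indexed by sample id (e.g.
    ``ClassificationResult.labels``). Patients with fewer than 2 classified
    samples are excluded from eligibility (a single region cannot disagree
    with itself).
    """
    rows = []
    for pid, samples in annot.samples_by_patient().items():
        classified = [s for s in samples if s in labels.index]
        if len(classified) < 2:
            continue
        pat_labels = tuple(labels.loc[classified])
        rows.append(
            {
                "patient_id": pid,
                "n_regions": len(classified),
                "labels": pat_labels,
                "concordant": len(set(pat_labels)) == 1,
            }
        )
    if not rows:
        raise ValidationError("no patient has >= 2 classified samples")
    per_patient = pd.DataFrame(rows).set_index("patient_id")
    discordant = (~per_patient["concordant"]).to_numpy()
    n_eligible = len(per_patient)
    rate = float(discordant.mean())

    rng = np.random.default_rng(seed)
    boot = discordant[rng.integers(0, n_eligible, size=(n_boot, n_eligible))].mean(axis=1)
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
    return ConcordanceReport(
        per_patient=per_patient,
        n_eligible=n_eligible,
        n_discordant=int(discordant.sum()),
        discordance_rate=rate,
        ci_low=float(lo),
        ci_high=float(hi),
        ci_level=ci_level,
        n_boot=n_boot,
        seed=seed,
    )


def compare_discordance(
    report_a: ConcordanceReport,
    report_b: ConcordanceReport,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> dict:
    """Paired comparison of two signatures' discordance over the same patients.

    Returns the rate difference (a minus b) with a paired patient-level
    bootstrap CI and an exact sign test over patients whose concordance flags
    disagree (binomial with p = 0.5 under no difference).
    """
    pa = set(report_a.per_patient.index)
    pb = set(report_b.per_patient.index)
    if pa != pb:
        raise ValidationError(
            f"patient sets differ: only-in-a={sorted(pa - pb)}, "
            f"only-in-b={sorted(pb - pa)}"
        )
    patients = list(report_a.per_patient.index)
    da = (~report_a.per_patient.loc[patients, "concordant"]).to_numpy()
    db = (~report_b.per_patient.loc[patients, "concordant"]).to_numpy()
    n = len(patients)
    delta = float(da.mean() - db.mean())

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = da[idx].mean(axis=1) - db[idx].mean(axis=1)
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])

    disagree = da != db
    n_disagree = int(disagree.sum())
    n_a_worse = int((da & ~db).sum())  # a discordant where b concordant
    p_sign = (
        1.0
        if n_disagree == 0
        else float(stats.binomtest(n_a_worse, n_disagree, 0.5).pvalue)
    )
    return {
        "delta": delta,
        "rate_a": float(da.mean()),
        "rate_b": float(db.mean()),
        "ci": [float(lo), float(hi)],
        "ci_level": ci_level,
        "n_patients": n,
        "n_disagree": n_disagree,
        "n_a_worse": n_a_worse,
        "sign_test_p": p_sign,
        "n_boot": n_boot,
        "seed": seed,
    }
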