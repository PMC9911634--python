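"""Core data containers and file I/O.

Tabular conventions used throughout the package:

* **Expression**: TSV, genes in rows, samples in columns; header row of sample
  ids, first column ``gene_id``. Values are expected on the log2(x+1) scale.
  The package never re-transforms expression silently — the scale is a user
  contract, not something inferred from the data.
* **Annotation**: TSV with at least ``sample_id``, ``patient_id``,
  ``region_id`` columns; extra columns are carried along untouched.
* **Gene sets**: standard GMT (name TAB description TAB gene TAB gene ...).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("ithsig")

REQUIRED_ANNOTATION_COLUMNS = ("sample_id", "patient_id", "region_id")

#: Cytotoxic / exhaustion markers used by default to anchor the immune factor
#: on human data (CD8 T-cell effectors, IFN-gamma axis, checkpoint genes).
DEFAULT_IMMUNE_MARKERS = (
    "CD8A", "CD8B", "GZMA", "GZMB", "PRF1",
    "IFNG", "CXCL9", "CXCL10", "CD274", "CTLA4",
)


class ValidationError(ValueError):
    """Input or configuration violates a documented contract."""


def configure_logging(level: str = "INFO") -> None:
    """Route package logs to stderr with timestamps; results go to files only."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    logger.handlers.clear()
    logger.addHandler(handler)
    logger.setLevel(level.upper())


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples numeric matrix with identifier bookkeeping.

    Wraps a pandas DataFrame (index = gene ids, columns = sample ids).
    Invariants enforced at construction: unique gene and sample ids, all
    values finite, and — unless ``allow_negative`` — non-negative (required
    by the NMF stage; log2(x+1) data is naturally non-negative).
    """

    data: pd.DataFrame
    allow_negative: bool = False

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression matrix contains non-numeric values")
        if not np.isfinite(values).all():
            raise ValidationError("expression matrix contains non-finite values")
        if not self.allow_negative and (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative expression value at gene {df.index[g]!r}, "
                f"sample {df.columns[s]!r}; pass allow_negative to permit"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing[:10]}")
        return replace(self, data=self.data.loc[list(genes)])


@dataclass(frozen=True)
class SampleAnnotation:
    """Sample -> patient -> region mapping for multi-region designs."""

    data: pd.DataFrame  # columns: sample_id, patient_id, region_id, extras

    def __post_init__(self) -> None:
        df = self.data
        for col in REQUIRED_ANNOTATION_COLUMNS:
            if col not in df.columns:
                raise ValidationError(f"annotation missing required column {col!r}")
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample_id values: {dupes}")
        pr = df[["patient_id", "region_id"]]
        if pr.duplicated().any():
            dupes = pr[pr.duplicated()].to_records(index=False).tolist()
            raise ValidationError(f"duplicate (patient_id, region_id) pairs: {dupes}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def patient_ids(self) -> list[str]:
        return list(pd.unique(self.data["patient_id"]))

    def samples_by_patient(self) -> dict[str, list[str]]:
        """Ordered mapping patient_id -> list of its sample ids."""
        out: dict[str, list[str]] = {}
        for pid, sub in self.data.groupby("patient_id", sort=False):
            out[str(pid)] = list(sub["sample_id"])
        return out

    def check_matches(self, expr: ExpressionMatrix) -> None:
        missing = set(self.data["sample_id"]) - set(expr.sample_ids)
        if missing:
            raise ValidationError(
                f"annotation samples absent from expression matrix: {sorted(missing)}"
            )


@dataclass(frozen=True)
class GeneSet:
    """Named gene list (GMT record)."""

    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the signature pipeline.

    Defaults mirror the published derivation where stated (500 top-loading
    genes, 2000 low-IHS genes, tertile split) and documented package choices
    elsewhere (NMF rank and convergence, event threshold, expression filter).
    """

    n_top_loading: int = 500
    n_low_ihs: int = 2000
    nmf_rank: int = 6
    nmf_restarts: int = 5
    nmf_max_iter: int = 500
    nmf_tol: float = 1e-5
    event_threshold_tau: float = 1.0  # log2 units
    expression_filter_min_mean: float = 1.0
    class_quantile: float = 2.0 / 3.0
    marker_genes: tuple[str, ...] = DEFAULT_IMMUNE_MARKERS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_top_loading < 1 or self.n_low_ihs < 1:
            raise ValidationError("n_top_loading and n_low_ihs must be >= 1")
        if not (0.0 < self.class_quantile < 1.0):
            raise ValidationError("class_quantile must lie strictly in (0, 1)")
        for name in ("nmf_rank", "nmf_restarts", "nmf_max_iter"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        if self.nmf_tol <= 0 or self.event_threshold_tau <= 0:
            raise ValidationError("nmf_tol and event_threshold_tau must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"config file {path} is not a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "marker_genes" in raw:
            raw["marker_genes"] = tuple(raw["marker_genes"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            f: (list(v) if isinstance(v := getattr(self, f), tuple) else v)
            for f in self.__dataclass_fields__
        }


# ---------------------------------------------------------------------------
# readers / writers


def read_expression_tsv(
    path: str | Path, require_nonnegative: bool = True
) -> ExpressionMatrix:
    """Read a genes-in-rows expression TSV into a validated matrix.

    Duplicate gene rows are collapsed by their mean (with a logged warning);
    duplicate sample columns are an error. Non-numeric cells raise an error
    naming the offending row and column.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = header[1:]
    seen: set[str] = set()
    for sid in sample_ids:
        if sid in seen:
            raise ValidationError(f"duplicate sample id in header: {sid!r}")
        seen.add(sid)

    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValidationError(
                f"non-numeric value at gene {gene!r}, sample {col!r}"
            )
        if coerced.isna().any():
            gene = df.index[coerced.isna().to_numpy().nonzero()[0][0]]
            raise ValidationError(f"missing value at gene {gene!r}, sample {col!r}")
        df[col] = coerced

    if df.index.has_duplicates:
        n_dupes = int(df.index.duplicated().sum())
        logger.warning(
            "collapsing %d duplicate gene rows by mean in %s", n_dupes, path.name
        )
        df = df.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(df, allow_negative=not require_nonnegative)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_annotation_tsv(path: str | Path) -> SampleAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in REQUIRED_ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise ValidationError(
                f"annotation file {Path(path).name} missing column {col!r}"
            )
    return SampleAnnotation(df)


def write_annotation_tsv(annot: SampleAnnotation, path: str | Path) -> None:
    annot.data.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file into gene sets; malformed lines raise with line number."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"GMT line {lineno} has {len(fields)} fields; need >= 3"
                )
            sets.append(GeneSet(fields[0], fields[1], tuple(fields[2:])))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")
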