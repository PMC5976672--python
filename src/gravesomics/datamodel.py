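"""Core containers and tabular I/O for the two-block omics pipeline.

Matrices are always features-in-rows, samples-in-columns: per-sample
normalisation (counts-per-million) is a column operation and every module
relies on this orientation. Protein non-detection is encoded as a literal
zero, never NaN, because the log-normalisation has an explicit zero branch.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_STATUS_LEVELS = ("control", "GD", "GO")
DEFAULT_CENTRE_LEVELS = ("Cardiff", "Essen", "Milan")


class Block(str, enum.Enum):
    MIRNA = "mirna"
    PROTEIN = "protein"
    COMBINED = "combined"


class Scale(str, enum.Enum):
    RAW_COUNTS = "raw_counts"
    RAW_ABUNDANCE = "raw_abundance"
    CPM = "cpm"
    LOG_ABUNDANCE = "log_abundance"
    STANDARDIZED = "standardized"


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


@dataclass
class OmicsMatrix:
    """Feature-by-sample numeric matrix with identity and scale metadata.

    Parameters
    ----------
    feature_ids, sample_ids
        Unique identifiers for rows and columns respectively.
    values
        Dense ``(n_features, n_samples)`` array. Raw miRNA counts must be
        non-negative integers; raw/log protein abundances must be finite
        and non-negative on the raw scale.
    block
        Which omics block the matrix belongs to.
    scale
        The measurement scale of ``values``.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    block: Block
    scale: Scale

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.block = Block(self.block)
        self.scale = Scale(self.scale)
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        nf, ns = self.values.shape
        if nf != len(self.feature_ids):
            raise ValidationError(
                f"{len(self.feature_ids)} feature ids but {nf} rows"
            )
        if ns != len(self.sample_ids):
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids but {ns} columns"
            )
        for axis_name, ids in (("feature", self.feature_ids),
                               ("sample", self.sample_ids)):
            dup = _duplicates(ids)
            if dup:
                raise ValidationError(f"duplicated {axis_name} ids: {sorted(dup)}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values must be finite")
        if self.scale is Scale.RAW_COUNTS:
            if np.any(self.values < 0):
                raise ValidationError("raw counts must be non-negative")
            if not np.allclose(self.values, np.round(self.values)):
                raise ValidationError("raw counts must be integers")
        if self.scale is Scale.RAW_ABUNDANCE and np.any(self.values < 0):
            raise ValidationError("raw abundances must be non-negative")

    # -- conveniences ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids,
                            columns=self.sample_ids)

    def subset_features(self, keep: list[str]) -> "OmicsMatrix":
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [idx[f] for f in keep]
        return OmicsMatrix(list(keep), list(self.sample_ids),
                           self.values[rows, :], self.block, self.scale)

    def reorder_samples(self, sample_ids: list[str]) -> "OmicsMatrix":
        """Return a copy with columns in the given order (sheet alignment)."""
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise ValidationError(f"samples absent from matrix: {missing}")
        cols = [idx[s] for s in sample_ids]
        return OmicsMatrix(list(self.feature_ids), list(sample_ids),
                           self.values[:, cols], self.block, self.scale)


@dataclass
class SampleSheet:
    """Per-sample design information: disease status and centre of origin."""

    sample_ids: list[str]
    status: list[str]
    centre: list[str]
    status_levels: tuple[str, ...] = DEFAULT_STATUS_LEVELS
    centre_levels: tuple[str, ...] = DEFAULT_CENTRE_LEVELS

    def __post_init__(self) -> None:
        dup = _duplicates(self.sample_ids)
        if dup:
            raise ValidationError(f"duplicated sample ids: {sorted(dup)}")
        if not (len(self.sample_ids) == len(self.status) == len(self.centre)):
            raise ValidationError("sample_ids, status and centre must align")
        bad = sorted(set(self.status) - set(self.status_levels))
        if bad:
            raise ValidationError(
                f"unknown status levels {bad}; allowed: {list(self.status_levels)}"
            )
        bad = sorted(set(self.centre) - set(self.centre_levels))
        if bad:
            raise ValidationError(
                f"unknown centre levels {bad}; allowed: {list(self.centre_levels)}"
            )

    def __len__(self) -> int:
        return len(self.sample_ids)

    def status_counts(self) -> dict[str, int]:
        return {lv: self.status.count(lv) for lv in self.status_levels}

    def require_classes(self, minimum: int = 2) -> None:
        """Fail unless at least `minimum` distinct status levels are present."""
        present = len(set(self.status))
        if present < minimum:
            raise ValidationError(
                f"need >= {minimum} status levels, found {present}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "status": self.status,
             "centre": self.centre}
        )

    def subset(self, index: np.ndarray) -> "SampleSheet":
        ids = [self.sample_ids[i] for i in index]
        st = [self.status[i] for i in index]
        ce = [self.centre[i] for i in index]
        return SampleSheet(ids, st, ce, self.status_levels, self.centre_levels)


@dataclass
class PathwayAnnotation:
    """One gene set: pathway id, free-text description, member gene symbols."""

    pathway_id: str
    description: str
    gene_symbols: frozenset[str]

    def __post_init__(self) -> None:
        self.gene_symbols = frozenset(self.gene_symbols)
        if not self.gene_symbols:
            raise ValidationError(f"pathway {self.pathway_id} has no genes")


@dataclass
class FeatureGeneMap:
    """Total map from feature ids (miRNA/protein) to gene symbols."""

    mapping: dict[str, str] = field(default_factory=dict)

    def genes_for(self, feature_ids) -> set[str]:
        return {self.mapping[f] for f in feature_ids if f in self.mapping}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_matrix(path, block: Block | str, scale: Scale | str) -> OmicsMatrix:
    """Read a feature-by-sample TSV (header = sample ids, col 0 = feature ids)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed TSV {path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValidationError(f"duplicated feature ids in {path}: {dups}")
    if df.columns.has_duplicates:
        raise ValidationError(f"duplicated sample ids in {path}")
    return OmicsMatrix(list(df.index.astype(str)), list(df.columns.astype(str)),
                       df.to_numpy(dtype=float), Block(block), Scale(scale))


def write_matrix(matrix: OmicsMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="feature_id",
                             float_format="%.10g")


def read_samplesheet(path, status_levels=DEFAULT_STATUS_LEVELS,
                     centre_levels=DEFAULT_CENTRE_LEVELS) -> SampleSheet:
    """Read a TSV with columns sample_id, status, centre."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"sample_id", "status", "centre"}
    if not needed <= set(df.columns):
        raise ValidationError(
            f"sample sheet must have columns {sorted(needed)}, "
            f"found {list(df.columns)}"
        )
    return SampleSheet(list(df["sample_id"]), list(df["status"]),
                       list(df["centre"]), tuple(status_levels),
                       tuple(centre_levels))


def write_samplesheet(sheet: SampleSheet, path) -> None:
    sheet.to_frame().to_csv(path, sep="\t", index=False)


def read_gmt(path) -> list[PathwayAnnotation]:
    """Read GMT: one pathway per line, tab-separated id, description, genes."""
    pathways: list[PathwayAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs id, description and "
                    f">=1 gene, found {len(fields)} fields"
                )
            pid, desc, *genes = fields
            if pid in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate pathway {pid}")
            seen.add(pid)
            pathways.append(PathwayAnnotation(pid, desc, frozenset(genes)))
    return pathways


def read_feature_gene_map(path) -> FeatureGeneMap:
    """Read a two-column TSV feature_id -> gene_symbol (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError("feature-gene map needs two columns")
    feats, genes = df.iloc[:, 0], df.iloc[:, 1]
    if feats.duplicated().any():
        dups = sorted(feats[feats.duplicated()].unique())
        raise ValidationError(f"feature mapped more than once: {dups}")
    return FeatureGeneMap(dict(zip(feats, genes)))


def align(matrix: OmicsMatrix, sheet: SampleSheet) -> OmicsMatrix:
    """Reorder matrix columns to the sheet's sample order.

    Every sheet sample must be present in the matrix; extra matrix columns
    are an error because the study requires complete two-block samples.
    """
    extra = set(matrix.sample_ids) - set(sheet.sample_ids)
    if extra:
        raise ValidationError(
            f"matrix samples not in sheet (incomplete design): {sorted(extra)}"
        )
    return matrix.reorder_samples(list(sheet.sample_ids))


def _duplicates(items) -> set:
    seen: set = set()
    dup: set = set()
    for it in items:
        if it in seen:
            dup.add(it)
        seen.add(it)
    return dup
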