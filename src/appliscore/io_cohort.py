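"""Readers, validation and joining for expression, clinical, signature and centroid inputs.

All tabular I/O is plain text (TSV/CSV, UTF-8, header row). Expression
matrices are genes-in-rows by default and hold log2 intensities. Clinical
tables are one row per sample with a declared dictionary of categorical
levels (:data:`CLINICAL_LEVELS`); missing values are ``NaN`` for continuous
variables and either ``NaN`` or the literal string ``missing`` for
categoricals (normalised to ``NaN`` on read).

Everything in this module is deterministic; randomised operations live
downstream and take explicit seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("appliscore")

#: Canonical order of the five intrinsic molecular subtypes. Used both for
#: validation and as the fixed tie-break order in subtype calling.
SUBTYPE_ORDER = ("Basal", "Her2", "LumA", "LumB", "Normal")

#: Declared level dictionaries for categorical clinical variables. Levels are
#: ordered; the first level is the reference for one-hot encoding and the
#: order defines the integer codes for ordinal encoding.
CLINICAL_LEVELS: Mapping[str, tuple[str, ...]] = {
    "er_status": ("negative", "positive"),
    "her2_status": ("negative", "positive"),
    "node_status": ("negative", "positive"),
    "stage": ("1", "2", "3"),
    "grade": ("1", "2", "3"),
    "subtype": SUBTYPE_ORDER,
    "response": ("RD", "pCR"),
    "chemo": ("no", "yes"),
    "radio": ("no", "yes"),
    "hormone": ("no", "yes"),
}

#: Continuous clinical variables (coerced to float on read).
CONTINUOUS_COLUMNS = ("age", "tumor_size", "time", "event")


def _sep_for(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene-by-sample matrix of log2 expression intensities.

    ``values`` is a DataFrame with gene (or probeset) identifiers as the row
    index and sample identifiers as columns. All cells must be finite and
    sample identifiers unique; gene identifiers may repeat only before
    probeset collapse.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        cols = self.values.columns
        if cols.duplicated().any():
            dupes = sorted(set(cols[cols.duplicated()]))
            raise ValueError(f"duplicate sample identifiers: {dupes}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr.astype(float)).all():
            raise ValueError("expression values must be finite (no missing cells)")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates, outcomes and treatment flags.

    ``data`` is indexed by sample identifier. Categorical columns must draw
    their values from :data:`CLINICAL_LEVELS`; ``time`` must be nonnegative
    and ``event`` in {0, 1} where present.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index
        if idx.duplicated().any():
            raise ValueError("duplicate sample identifiers in clinical table")
        for col, levels in CLINICAL_LEVELS.items():
            if col in self.data.columns:
                vals = self.data[col].dropna()
                bad = set(vals.unique()) - set(levels)
                if bad:
                    raise ValueError(
                        f"clinical column {col!r} has undeclared levels {sorted(bad)}; "
                        f"allowed: {levels}"
                    )
        if "time" in self.data.columns:
            t = pd.to_numeric(self.data["time"], errors="raise")
            if (t.dropna() < 0).any():
                raise ValueError("survival time must be nonnegative")
        if "event" in self.data.columns:
            e = pd.to_numeric(self.data["event"], errors="raise").dropna()
            if not e.isin([0, 1]).all():
                raise ValueError("event indicator must be 0 (censored) or 1 (event)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class Cohort:
    """A clinical table optionally joined with an expression matrix.

    The universal unit of work downstream. When expression is present its
    samples equal (and are ordered as) the clinical samples.
    """

    clinical: ClinicalTable
    expression: ExpressionMatrix | None = None
    name: str = "cohort"

    def __post_init__(self) -> None:
        if self.expression is not None:
            if self.expression.sample_ids != self.clinical.sample_ids:
                raise ValueError(
                    "expression and clinical sample identifiers differ; "
                    "use join_cohort() to align them"
                )

    @property
    def sample_ids(self) -> list[str]:
        return self.clinical.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.clinical.data)


@dataclass
class GeneSignature:
    """A named gene list with per-gene weights driving a per-sample score."""

    name: str
    genes: tuple[str, ...]
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.weights is None:
            self.weights = np.ones(len(self.genes))
        self.weights = np.asarray(self.weights, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} lists a gene more than once")
        if len(self.weights) != len(self.genes):
            raise ValueError("one weight per gene required")
        if not np.isfinite(self.weights).all():
            raise ValueError("signature weights must be finite")


@dataclass
class CentroidProfiles:
    """Centroid expression profiles, one column per molecular subtype."""

    values: pd.DataFrame  # genes x subtypes

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate subtype names in centroid profiles")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("centroid values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def subtype_names(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_expression(
    path: str | Path,
    id_column: str | None = None,
    genes_in_rows: bool = True,
    sep: str | None = None,
) -> ExpressionMatrix:
    """Read a TSV/CSV expression matrix (one row per probeset/gene by default).

    ``id_column`` names the identifier column; by default the first column is
    used. Set ``genes_in_rows=False`` for transposed input. Duplicate sample
    headers, non-numeric cells and missing cells are rejected.
    """
    path = Path(path)
    sep = _sep_for(path, sep)
    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline()
    if not header_line.strip():
        raise ValueError(f"{path}: no data rows")
    header = header_line.rstrip("\r\n").split(sep)
    body = [c for c in header[1:]]
    if len(body) != len(set(body)):
        dupes = sorted({c for c in body if body.count(c) > 1})
        raise ValueError(f"{path}: duplicated sample header {dupes}")

    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    id_col = id_column if id_column is not None else df.columns[0]
    if id_col not in df.columns:
        raise ValueError(f"{path}: id column {id_col!r} not found")
    df = df.set_index(id_col)
    df.index = df.index.astype(str)
    df.index.name = None

    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"{path}: non-numeric cell at row {row!r}, column {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        if converted.isna().any():
            row = df.index[converted.isna().to_numpy().argmax()]
            raise ValueError(f"{path}: missing cell at row {row!r}, column {col!r}")
        numeric[col] = converted
    if not genes_in_rows:
        numeric = numeric.T
    return ExpressionMatrix(numeric)


def write_expression(matrix: ExpressionMatrix, path: str | Path, id_column: str = "gene") -> None:
    """Write an expression matrix as tab-delimited UTF-8 with a header row."""
    out = matrix.values.copy()
    out.index.name = id_column
    out.to_csv(path, sep="\t", encoding="utf-8")


def read_clinical(path: str | Path, sep: str | None = None, id_column: str | None = None) -> ClinicalTable:
    """Read a per-sample clinical table; coerces continuous columns to float
    and normalises the literal level ``missing`` to ``NaN``."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    id_col = id_column if id_column is not None else df.columns[0]
    df = df.set_index(id_col)
    df.index = df.index.astype(str)
    df = df.replace({"missing": np.nan, "": np.nan, "NA": np.nan})
    for col in CONTINUOUS_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path: str | Path, id_column: str = "sample_id") -> None:
    out = table.data.copy()
    out.index.name = id_column
    out.to_csv(path, sep="\t", encoding="utf-8")


def read_signature(path: str | Path, format: str | None = None) -> GeneSignature:
    """Read a gene signature from a GMT line or a two-column (gene, weight) TSV.

    GMT: ``name<TAB>description<TAB>gene1<TAB>gene2...`` — weights default to
    1.0. TSV: header row then one ``gene<TAB>weight`` row per gene (signed
    weights preserved).
    """
    path = Path(path)
    if format is None:
        format = "gmt" if path.suffix.lower() == ".gmt" else "tsv"
    if format == "gmt":
        with open(path, "r", encoding="utf-8") as fh:
            line = fh.readline().rstrip("\r\n")
        if not line:
            raise ValueError(f"{path}: empty GMT file")
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: GMT line needs name, description and >=1 gene")
        name, genes = parts[0], tuple(parts[2:])
        return GeneSignature(name=name, genes=genes)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        if df.shape[1] < 2:
            raise ValueError(f"{path}: signature TSV needs gene and weight columns")
        genes = tuple(df.iloc[:, 0].astype(str))
        weights = df.iloc[:, 1].astype(float).to_numpy()
        return GeneSignature(name=path.stem, genes=genes, weights=weights)
    raise ValueError(f"unknown signature format {format!r}")


def read_centroids(path: str | Path, sep: str | None = None) -> CentroidProfiles:
    """Read centroid profiles: gene rows, one column per subtype."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return CentroidProfiles(df.astype(float))


def write_centroids(centroids: CentroidProfiles, path: str | Path) -> None:
    out = centroids.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", encoding="utf-8")


# ---------------------------------------------------------------------------
# Probeset collapse and cohort joining
# ---------------------------------------------------------------------------


def collapse_probesets(
    matrix: ExpressionMatrix, probe_to_gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse probeset rows to one row per gene.

    For a gene measured by several probesets, the representative row is the
    probeset with the highest mean intensity across all samples. Probesets
    without a mapping are dropped. Ties on the mean keep the probeset that
    appears first in input order (logged).
    """
    if not probe_to_gene:
        raise ValueError("empty probeset-to-gene mapping")
    df = matrix.values
    mapped = [p for p in df.index if p in probe_to_gene]
    n_dropped = len(df.index) - len(mapped)
    if n_dropped:
        logger.info("collapse_probesets: dropped %d unmapped probesets", n_dropped)
    if not mapped:
        raise ValueError("no probesets left after applying the mapping")

    means = df.loc[mapped].mean(axis=1)
    best_probe: dict[str, str] = {}
    gene_order: list[str] = []
    for probe in mapped:  # input order; strict > keeps the first on ties
        gene = probe_to_gene[probe]
        if gene not in best_probe:
            best_probe[gene] = probe
            gene_order.append(gene)
        elif means[probe] > means[best_probe[gene]]:
            best_probe[gene] = probe
        elif means[probe] == means[best_probe[gene]]:
            logger.info(
                "collapse_probesets: tie on mean intensity for gene %s "
                "(%s kept over %s)", gene, best_probe[gene], probe,
            )
    rows = df.loc[[best_probe[g] for g in gene_order]].to_numpy()
    collapsed = pd.DataFrame(rows, index=gene_order, columns=df.columns)
    return ExpressionMatrix(collapsed)


def join_cohort(
    expression: ExpressionMatrix | None,
    clinical: ClinicalTable,
    name: str = "cohort",
) -> Cohort:
    """Join expression and clinical tables on their shared samples.

    The cohort is restricted to the intersection of sample identifiers
    (matched case-sensitively), ordered as in the clinical table; dropped
    samples are logged. With no expression the cohort is clinical-only.
    """
    if expression is None:
        return Cohort(clinical=clinical, expression=None, name=name)
    expr_ids = set(expression.sample_ids)
    keep = [s for s in clinical.sample_ids if s in expr_ids]
    if not keep:
        raise ValueError("expression and clinical tables share no samples")
    dropped_clin = [s for s in clinical.sample_ids if s not in expr_ids]
    dropped_expr = [s for s in expression.sample_ids if s not in set(keep)]
    if dropped_clin or dropped_expr:
        logger.info(
            "join_cohort: dropped %d clinical-only and %d expression-only samples: %s",
            len(dropped_clin), len(dropped_expr),
            sorted(dropped_clin + dropped_expr),
        )
    clin = ClinicalTable(clinical.data.loc[keep])
    expr = ExpressionMatrix(expression.values.loc[:, keep])
    return Cohort(clinical=clin, expression=expr, name=name)
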