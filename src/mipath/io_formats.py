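"""Readers, writers and validators for the file formats the tool touches.

Expression matrices are oriented samples x genes everywhere in the package;
a single ``transpose`` flag at ingest covers genes x samples sources.  Gene
identifiers are matched between gene sets and the matrix by exact,
case-sensitive string equality; no symbol/ID translation is attempted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sparse

logger = logging.getLogger("mipath")

__all__ = [
    "ExpressionMatrix",
    "PathwayCollection",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_phenotype",
    "align_inputs",
]


def _check_unique(ids, what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = sorted(set(seen[seen.duplicated()]))
        raise ValueError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionMatrix:
    """A samples x genes numeric matrix with row and column identifiers.

    ``values`` may be a dense :class:`numpy.ndarray` or a scipy sparse
    matrix; sparse inputs stay sparse through subsetting so that large
    single-cell matrices remain tractable.  Missing entries in sparse input
    are zeros by definition; NaN is never allowed.
    """

    values: np.ndarray | sparse.spmatrix
    sample_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        n, p = self.values.shape
        if len(self.sample_ids) != n or len(self.gene_ids) != p:
            raise ValueError(
                f"identifier/shape mismatch: values {self.values.shape}, "
                f"{len(self.sample_ids)} sample ids, {len(self.gene_ids)} gene ids"
            )
        _check_unique(self.sample_ids, "sample ids")
        _check_unique(self.gene_ids, "gene ids")
        if sparse.issparse(self.values):
            if np.isnan(self.values.data).any():
                raise ValueError("expression matrix contains NaN")
        elif np.isnan(np.asarray(self.values, dtype=float)).any():
            raise ValueError("expression matrix contains NaN")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def dense(self) -> np.ndarray:
        if sparse.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def subset_samples(self, index: np.ndarray) -> "ExpressionMatrix":
        vals = self.values[index]
        ids = [self.sample_ids[i] for i in index]
        return ExpressionMatrix(vals, ids, list(self.gene_ids))

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Restrict columns to ``genes`` (kept in matrix order)."""
        wanted = set(genes)
        idx = [j for j, g in enumerate(self.gene_ids) if g in wanted]
        vals = self.values[:, idx] if len(idx) else self.values[:, :0]
        return ExpressionMatrix(vals, list(self.sample_ids), [self.gene_ids[j] for j in idx])


@dataclass
class PathwayCollection:
    """Named gene sets, in file order, mapped to gene identifier sets."""

    pathways: dict[str, set[str]] = field(default_factory=dict)
    source_label: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {name!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways.items())

    def __getitem__(self, name: str) -> set[str]:
        return self.pathways[name]


def read_expression(
    path: str | Path,
    format: str = "csv",
    transpose: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from CSV/TSV or a Matrix Market directory.

    CSV/TSV layout: header row of gene identifiers, first column of sample
    identifiers.  ``mtx_dir`` expects ``matrix.mtx`` plus ``rows.txt`` and
    ``cols.txt`` sidecars (one identifier per line; rows are samples unless
    ``transpose``).  Non-numeric or missing cells are hard errors reported
    with their location.
    """
    path = Path(path)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        bad = df.map(lambda v: not isinstance(v, (int, float, np.number)) or pd.isna(v))
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"non-numeric or missing cell at sample {df.index[r]!r}, "
                f"gene {df.columns[c]!r} in {path}"
            )
        values = df.to_numpy(dtype=float)
        sample_ids = [str(s) for s in df.index]
        gene_ids = [str(g) for g in df.columns]
    elif format == "mtx_dir":
        mtx = next(iter(sorted(path.glob("*.mtx"))), None)
        if mtx is None:
            raise FileNotFoundError(f"no .mtx file in {path}")
        values = sparse.csr_matrix(scipy.io.mmread(mtx))
        sample_ids = (path / "rows.txt").read_text().split()
        gene_ids = (path / "cols.txt").read_text().split()
    else:
        raise ValueError(f"unknown expression format {format!r}")

    if transpose:
        values = values.T
        sample_ids, gene_ids = gene_ids, sample_ids
    return ExpressionMatrix(values, list(sample_ids), list(gene_ids))


def write_expression(expr: ExpressionMatrix, path: str | Path, sep: str = ",") -> None:
    df = pd.DataFrame(expr.dense(), index=expr.sample_ids, columns=expr.gene_ids)
    df.to_csv(path, sep=sep)


def read_gmt(path: str | Path, source_label: str | None = None) -> PathwayCollection:
    """Parse a GMT gene-set file: ``name<TAB>description<TAB>gene...`` per line.

    The description field is discarded, duplicate genes within a line are
    deduplicated, and lines with no genes are skipped with a warning.
    Duplicate pathway names are a hard error.
    """
    path = Path(path)
    pathways: dict[str, set[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.rstrip()
        if not line:
            continue
        parts = line.split("\t")
        name = parts[0]
        genes = {g for g in parts[2:] if g}
        if not genes:
            warnings.warn(f"{path.name}:{lineno}: pathway {name!r} has no genes; skipped")
            continue
        if name in pathways:
            raise ValueError(f"{path.name}:{lineno}: duplicate pathway name {name!r}")
        pathways[name] = genes
    return PathwayCollection(pathways, source_label or path.stem)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            fh.write("\t".join([name, collection.source_label, *sorted(genes)]) + "\n")


def read_phenotype(path: str | Path, sample_col: str = "sample_id") -> pd.DataFrame:
    """Read a TSV phenotype table into a DataFrame indexed by sample id.

    Every column is treated as a discrete label; missing labels and
    duplicate sample ids are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if sample_col not in df.columns:
        raise ValueError(f"phenotype table lacks a {sample_col!r} column")
    df = df.set_index(sample_col)
    _check_unique(df.index, "phenotype sample ids")
    if df.isna().any().any():
        missing = df.columns[df.isna().any()].tolist()
        raise ValueError(f"missing labels in phenotype column(s) {missing}")
    return df


def align_inputs(
    expr: ExpressionMatrix, pheno: pd.DataFrame
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Restrict both inputs to their shared samples, in expression order."""
    shared = set(expr.sample_ids) & set(pheno.index)
    if not shared:
        raise ValueError("expression matrix and phenotype table share no samples")
    keep = np.array([i for i, s in enumerate(expr.sample_ids) if s in shared])
    dropped = (len(expr.sample_ids) - len(keep)) + (len(pheno) - len(shared))
    if dropped:
        logger.info("align_inputs: dropped %d unmatched sample(s)", dropped)
    expr2 = expr.subset_samples(keep)
    return expr2, pheno.loc[expr2.sample_ids]
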