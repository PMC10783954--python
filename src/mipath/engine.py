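"""Pipeline orchestration: per-pathway scoring, FDR annotation and ranking.

For each pathway the expression matrix is restricted to the pathway's genes
(z-scored per gene), a directed kNN graph is built over samples in that
subspace, SNN-weighted, and clustered into modules; the module partition is
then scored against the phenotype partition with (conditional) AMI, and a
permutation p-value is attached with the module partition held fixed.
Pathways are independent units of work: each derives its own seed from the
master seed and the pathway name, so iteration order and scheduling never
change results.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sparse

from .clustering import detect_modules
from .graph import build_knn, snn_weights
from .infoscore import (
    ScoreResult,
    ami,
    as_labels,
    conditional_ami,
    permutation_test,
    qvalues,
)
from .io_formats import ExpressionMatrix, PathwayCollection

logger = logging.getLogger("mipath")

__all__ = [
    "RunConfig",
    "PathwayScore",
    "normalize_genes",
    "score_pathway",
    "score_all",
    "subsample_reproducibility",
]


@dataclass
class RunConfig:
    """Pipeline parameters.

    k is the number of nearest neighbors (default 25, the method's default);
    n_permutations sizes the empirical null (default 10 000; 0 disables
    p-values); pathways matching fewer than min_pathway_genes genes are
    skipped; resolution is the modularity resolution (1.0 = classic).
    """

    k: int = 25
    n_permutations: int = 10_000
    min_pathway_genes: int = 5
    resolution: float = 1.0
    seed: int = 0
    normalization: str = "zscore"  # zscore | none
    neighbor_mode: str = "auto"  # auto | exact | approximate
    condition_column: str | None = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_permutations < 0:
            raise ValueError("n_permutations must be >= 0")


@dataclass
class PathwayScore:
    """One row of the output table."""

    pathway: str
    n_genes_used: int
    n_modules: int
    ami: float
    p_value: float | None
    q_value: float | None = None
    rank: float | None = None
    status: str = "ok"
    result: ScoreResult | None = field(default=None, repr=False)


def normalize_genes(expr: ExpressionMatrix, method: str = "zscore") -> ExpressionMatrix:
    """Z-score each gene column (population SD); ``none`` is the identity.

    Zero-variance genes become all-zero columns (with a warning) and thus
    contribute nothing to the Euclidean distances downstream.  Sparse input
    is densified here; the per-pathway path in :func:`score_all` instead
    normalizes each small pathway submatrix from precomputed sparse-aware
    gene statistics.
    """
    if method == "none":
        return expr
    if method != "zscore":
        raise ValueError(f"unknown normalization {method!r}")
    x = expr.dense()
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance gene(s) set to all-zeros")
    sd = np.where(flat, 1.0, sd)
    z = (x - mu) / sd
    z[:, flat] = 0.0
    return ExpressionMatrix(z, list(expr.sample_ids), list(expr.gene_ids))


def _gene_stats(expr: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean and population SD without densifying a sparse matrix."""
    v = expr.values
    if sparse.issparse(v):
        mu = np.asarray(v.mean(axis=0)).ravel()
        ex2 = np.asarray(v.multiply(v).mean(axis=0)).ravel()
        sd = np.sqrt(np.maximum(ex2 - mu**2, 0.0))
    else:
        x = np.asarray(v, dtype=float)
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
    return mu, sd


def derive_seed(master_seed: int, token: str) -> int:
    """Stable per-pathway seed from the master seed and the pathway name."""
    digest = hashlib.blake2b(f"{master_seed}|{token}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") & 0x7FFFFFFF


def _pathway_submatrix(
    expr: ExpressionMatrix, gene_idx: np.ndarray, mu: np.ndarray, sd: np.ndarray, method: str
) -> np.ndarray:
    sub = expr.values[:, gene_idx]
    sub = np.asarray(sub.todense(), dtype=float) if sparse.issparse(sub) else np.asarray(sub, dtype=float)
    if method == "none":
        return sub
    s = sd[gene_idx]
    z = (sub - mu[gene_idx]) / np.where(s == 0, 1.0, s)
    z[:, s == 0] = 0.0
    return z


def score_pathway(
    expr: ExpressionMatrix,
    genes,
    phenotype,
    config: RunConfig,
    confounder=None,
    pathway_name: str = "",
    _stats: tuple[np.ndarray, np.ndarray] | None = None,
) -> PathwayScore:
    """Score one pathway's module structure against the phenotype.

    ``expr`` is the full (unnormalized) matrix; genes absent from it are
    ignored and the number actually used is reported.  Pathways matching
    fewer than ``config.min_pathway_genes`` genes are returned with a
    ``skipped:`` status rather than raising.
    """
    name = pathway_name or "pathway"
    gene_idx = np.flatnonzero(np.isin(np.asarray(expr.gene_ids, dtype=object), list(genes)))
    n_used = len(gene_idx)
    if n_used < config.min_pathway_genes:
        logger.warning("%s: only %d matching gene(s); skipped", name, n_used)
        return PathwayScore(name, n_used, 0, float("nan"), None, status="skipped:too_few_genes")
    if config.k >= expr.n_samples:
        raise ValueError(f"k={config.k} must be smaller than n_samples={expr.n_samples}")

    mu, sd = _stats if _stats is not None else _gene_stats(expr)
    points = _pathway_submatrix(expr, gene_idx, mu, sd, config.normalization)
    seed = derive_seed(config.seed, name)
    adj = build_knn(points, config.k, mode=config.neighbor_mode, seed=seed)
    graph = snn_weights(adj, config.k)
    modules = detect_modules(graph, resolution=config.resolution, seed=seed)

    pheno = as_labels(phenotype)
    cond = as_labels(confounder) if confounder is not None else None
    if cond is None:
        result = ami(modules, pheno)
    else:
        result = conditional_ami(modules, pheno, cond)
    p_value = None
    if config.n_permutations > 0:
        p_value, _ = permutation_test(
            modules, pheno, config.n_permutations, seed=seed, conditional_on=cond
        )
        result.p_value = p_value
    return PathwayScore(
        pathway=name,
        n_genes_used=n_used,
        n_modules=int(modules.max()) + 1,
        ami=result.ami,
        p_value=p_value,
        status="ok",
        result=result,
    )


def score_all(
    expr: ExpressionMatrix,
    pathways: PathwayCollection,
    pheno: pd.DataFrame,
    config: RunConfig,
    phenotype_column: str | None = None,
) -> pd.DataFrame:
    """Score every pathway and return the ranked, FDR-annotated table.

    Columns: pathway, n_genes_used, n_modules, ami, p_value, q_value, rank,
    status.  Ranks are tied-average on AMI descending (rank 1 = highest
    score); q-values are Storey-adjusted across the retained pathways.
    """
    col = phenotype_column or pheno.columns[0]
    phenotype = pheno[col].to_numpy()
    confounder = (
        pheno[config.condition_column].to_numpy() if config.condition_column else None
    )
    mu, sd = _gene_stats(expr)
    rows: list[PathwayScore] = []
    for i, (name, genes) in enumerate(pathways):
        rows.append(
            score_pathway(
                expr, genes, phenotype, config,
                confounder=confounder, pathway_name=name, _stats=(mu, sd),
            )
        )
        logger.info("[%d/%d] %s: %s", i + 1, len(pathways), name, rows[-1].status)
    df = pd.DataFrame(
        {
            "pathway": [r.pathway for r in rows],
            "n_genes_used": [r.n_genes_used for r in rows],
            "n_modules": [r.n_modules for r in rows],
            "ami": [r.ami for r in rows],
            "p_value": [r.p_value if r.p_value is not None else np.nan for r in rows],
            "status": [r.status for r in rows],
        }
    ).set_index("pathway")
    ok = df["status"] == "ok"
    if not ok.any():
        raise ValueError("no pathway passed the gene-matching threshold")
    df["q_value"] = np.nan
    if config.n_permutations > 0:
        df.loc[ok, "q_value"] = qvalues(df.loc[ok, "p_value"].to_numpy())
    df["rank"] = np.nan
    df.loc[ok, "rank"] = df.loc[ok, "ami"].rank(ascending=False, method="average")
    return df[["n_genes_used", "n_modules", "ami", "p_value", "q_value", "rank", "status"]]


def subsample_reproducibility(
    expr: ExpressionMatrix,
    pathways: PathwayCollection,
    pheno: pd.DataFrame,
    config: RunConfig,
    fraction: float = 0.2,
    n_repeats: int = 10,
    phenotype_column: str | None = None,
) -> tuple[float, np.ndarray]:
    """Score stability under repeated uniform subsampling of the samples.

    Runs :func:`score_all` on ``n_repeats`` independent subsamples of the
    given fraction and returns the mean Pearson correlation between all
    pairs of pathway AMI vectors, plus the full pairwise correlation matrix.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    n = expr.n_samples
    size = int(round(fraction * n))
    if size < config.k + 1:
        raise ValueError(
            f"subsample of {size} samples is too small for k={config.k}"
        )
    vectors = []
    for r in range(n_repeats):
        rng = np.random.default_rng(derive_seed(config.seed, f"subsample:{r}"))
        idx = np.sort(rng.choice(n, size=size, replace=False))
        sub_expr = expr.subset_samples(idx)
        sub_pheno = pheno.loc[sub_expr.sample_ids]
        sub_config = replace(config, seed=derive_seed(config.seed, f"run:{r}"))
        table = score_all(sub_expr, pathways, sub_pheno, sub_config, phenotype_column)
        vectors.append(table.loc[table["status"] == "ok", "ami"])
    common = vectors[0].index
    for v in vectors[1:]:
        common = common.intersection(v.index)
    mat = np.corrcoef(np.vstack([v.loc[common].to_numpy() for v in vectors]))
    pairs = mat[np.triu_indices(n_repeats, k=1)]
    return float(pairs.mean()), mat
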