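"""Seeded synthetic expression datasets with planted pathway-phenotype signal.

The generator emulates the structure the method assumes: samples cluster
differently depending on which gene subspace is used.  Signal genes shift
their mean between phenotype groups by ``effect_size`` (in within-group SD
units, the residual SD being 1); noise genes are standard normal everywhere.
The pathway collection contains one "signal" pathway (exactly the signal
genes) plus size-matched decoy pathways drawn from the noise genes.
Optional single-cell-style dropout zeroes entries independently, and an
optional confounder Z drives a separate "confounded" gene block, allowing
both the no-confounding control (Y independent of Z) and the spurious-
association scenario (Y correlated with Z but conditionally independent of
the confounded pathway given Z).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, PathwayCollection

__all__ = ["SynthSpec", "generate", "generate_confounded"]


@dataclass
class SynthSpec:
    """Parameters of a synthetic dataset.

    Defaults describe the standard planted-signal benchmark: 1000 samples in
    two equal phenotype groups, a 20-gene signal pathway shifted by 2 SD
    between groups, 500 noise genes and 50 matched decoy pathways, no
    dropout.
    """

    n_samples: int = 1000
    n_groups: int = 2
    group_sizes: list[int] | None = None
    n_signal_genes: int = 20
    n_noise_genes: int = 500
    effect_size: float = 2.0
    dropout_rate: float = 0.0
    n_decoy_pathways: int = 50
    confounder_groups: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_sizes is None:
            base, extra = divmod(self.n_samples, self.n_groups)
            self.group_sizes = [base + (i < extra) for i in range(self.n_groups)]
        if sum(self.group_sizes) != self.n_samples:
            raise ValueError("group_sizes must sum to n_samples")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.n_signal_genes < 1 or self.n_noise_genes < 0:
            raise ValueError("infeasible gene counts")
        if self.n_decoy_pathways > 0 and self.n_noise_genes < self.n_signal_genes:
            raise ValueError("too few noise genes to draw size-matched decoys")


def _group_labels(sizes: list[int], prefix: str) -> np.ndarray:
    return np.concatenate([[f"{prefix}{g}"] * s for g, s in enumerate(sizes)])


def _signal_block(rng, groups: np.ndarray, n_genes: int, effect: float) -> np.ndarray:
    """Gaussian block whose per-group means are effect * N(0,1) offsets."""
    levels, inv = np.unique(groups, return_inverse=True)
    offsets = rng.standard_normal((len(levels), n_genes)) * effect
    return offsets[inv] + rng.standard_normal((len(groups), n_genes))


def _assemble(spec: SynthSpec, rng, y: np.ndarray, z: np.ndarray | None,
              signal_effect: float | None = None):
    if signal_effect is None:
        signal_effect = spec.effect_size
    blocks, gene_ids = [], []
    blocks.append(_signal_block(rng, y, spec.n_signal_genes, signal_effect))
    signal_genes = [f"sig{i}" for i in range(spec.n_signal_genes)]
    gene_ids += signal_genes

    confounded_genes: list[str] = []
    if z is not None:
        blocks.append(_signal_block(rng, z, spec.n_signal_genes, spec.effect_size))
        confounded_genes = [f"conf{i}" for i in range(spec.n_signal_genes)]
        gene_ids += confounded_genes

    blocks.append(rng.standard_normal((spec.n_samples, spec.n_noise_genes)))
    noise_genes = [f"noise{i}" for i in range(spec.n_noise_genes)]
    gene_ids += noise_genes

    values = np.hstack(blocks)
    if spec.dropout_rate > 0:
        values[rng.random(values.shape) < spec.dropout_rate] = 0.0

    sample_ids = [f"s{i}" for i in range(spec.n_samples)]
    expr = ExpressionMatrix(values, sample_ids, gene_ids)

    pathways: dict[str, set[str]] = {"signal": set(signal_genes)}
    if confounded_genes:
        pathways["confounded"] = set(confounded_genes)
    for d in range(spec.n_decoy_pathways):
        picked = rng.choice(spec.n_noise_genes, size=spec.n_signal_genes, replace=False)
        pathways[f"decoy{d}"] = {noise_genes[j] for j in picked}

    cols = {"group": y}
    if z is not None:
        cols["confounder"] = z
    pheno = pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample_id"))
    return expr, pheno, PathwayCollection(pathways, "synthetic")


def generate(spec: SynthSpec):
    """Planted-signal dataset; any confounder Z is independent of phenotype Y.

    Returns (ExpressionMatrix, phenotype DataFrame, PathwayCollection).  The
    phenotype table has a ``group`` column and, when ``confounder_groups``
    is set, an independent ``confounder`` column driving the "confounded"
    gene block — the no-confounding control.
    """
    rng = np.random.default_rng(spec.seed)
    y = _group_labels(spec.group_sizes, "g")
    z = None
    if spec.confounder_groups is not None:
        z = rng.permutation(
            _group_labels(
                [spec.n_samples // spec.confounder_groups
                 + (i < spec.n_samples % spec.confounder_groups)
                 for i in range(spec.confounder_groups)],
                "z",
            )
        )
    return _assemble(spec, rng, y, z)


def generate_confounded(spec: SynthSpec, coupling: float = 0.9):
    """Spurious-association dataset: Z drives both a gene block and Y.

    Each sample copies its confounder level into the phenotype with
    probability ``coupling`` and draws a uniform group otherwise, so the
    "confounded" pathway's genes depend only on Z while Y is correlated
    with Z but conditionally independent of those genes given Z.  With
    ``coupling=0`` this reduces to the independent control.
    """
    if spec.confounder_groups is None:
        raise ValueError("generate_confounded requires confounder_groups")
    if not 0 <= coupling <= 1:
        raise ValueError("coupling must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    z = rng.permutation(
        _group_labels(
            [spec.n_samples // spec.confounder_groups
             + (i < spec.n_samples % spec.confounder_groups)
             for i in range(spec.confounder_groups)],
            "z",
        )
    )
    z_codes = np.array([int(v[1:]) for v in z]) % spec.n_groups
    copy = rng.random(spec.n_samples) < coupling
    y_codes = np.where(copy, z_codes, rng.integers(0, spec.n_groups, spec.n_samples))
    y = np.array([f"g{c}" for c in y_codes])
    # phenotype carries no expression signal of its own: the only route from
    # any gene block to Y is through Z, so the "signal" pathway is pure noise
    return _assemble(spec, rng, y, z, signal_effect=0.0)
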