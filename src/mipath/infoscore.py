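"""Information-theoretic association scores between two sample partitions.

Mutual information between two discrete partitions X and Y is computed from
their empirical contingency table,

    MI(X, Y) = sum_ij (n_ij / n) * ln( n * n_ij / (a_i * b_j) ),

equivalently H(X) + H(Y) - H(X, Y), in nats.  Normalizing by the attainable
maximum maxMI = (H(X) + H(Y)) / 2 gives NMI in [0, 1].  Because MI between
random partitions with fixed margins is positive in expectation (and grows
with the number of groups), scores are chance-adjusted:

    AMI = (MI - E[MI]) / (maxMI - E[MI]),

where E[MI] is the exact expectation under the permutation model: cell
counts n_ij follow a (generalized) hypergeometric law given the margins, so
the expectation is a finite sum over each cell's support, evaluated with
log-factorials for stability.

The conditional variants stratify on a third partition Z: MI(X,Y|Z) is the
p(z)-weighted sum of within-stratum MI, maxMI(X,Y|Z) = (H(X|Z)+H(Y|Z))/2,
and E[MI(X,Y|Z)] combines within-stratum hypergeometric expectations with
the same p(z) weights.  Significance comes from label permutations (within
strata for the conditional score) with the module partition held fixed, and
multiple testing is controlled with Storey q-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ContingencyTable",
    "ScoreResult",
    "as_labels",
    "contingency",
    "entropy",
    "mutual_information",
    "expected_mi",
    "ami",
    "conditional_ami",
    "permutation_test",
    "mi_variance",
    "qvalues",
]

EXHAUSTIVE_LIMIT = 9  # largest n for which n! enumeration in mi_variance is allowed


@dataclass
class ContingencyTable:
    """Joint label counts n_ij with margins a_i (rows) and b_j (columns)."""

    counts: np.ndarray
    row_margins: np.ndarray
    col_margins: np.ndarray
    n: int


@dataclass
class ScoreResult:
    """MI and its normalized/chance-adjusted forms, all MI terms in nats."""

    mi: float
    nmi: float
    ami: float
    expected_mi: float
    max_mi: float
    n_modules_x: int
    n_modules_y: int
    p_value: float | None = None
    q_value: float | None = None


def as_labels(values) -> np.ndarray:
    """Encode an arbitrary discrete label sequence as integers 0..G-1."""
    values = np.asarray(values)
    _, inv = np.unique(values, return_inverse=True)
    return inv.astype(np.int64)


def contingency(x, y) -> ContingencyTable:
    x = as_labels(x)
    y = as_labels(y)
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"partition length mismatch: {x.shape[0]} vs {y.shape[0]}")
    r, c = int(x.max()) + 1, int(y.max()) + 1
    counts = np.bincount(x * c + y, minlength=r * c).reshape(r, c)
    return ContingencyTable(
        counts=counts,
        row_margins=counts.sum(axis=1),
        col_margins=counts.sum(axis=0),
        n=int(counts.sum()),
    )


def entropy(margins, n: int) -> float:
    """Shannon entropy (nats) of empirical frequencies margins / n."""
    p = np.asarray(margins, dtype=float) / n
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def mutual_information(table: ContingencyTable) -> float:
    """Plug-in MI of the table, in nats; 0*ln(0) terms are 0."""
    if table.n < 1:
        raise ValueError("empty contingency table")
    nz = table.counts > 0
    nij = table.counts[nz].astype(float)
    outer = np.outer(table.row_margins, table.col_margins)[nz].astype(float)
    mi = (nij / table.n * np.log(table.n * nij / outer)).sum()
    return max(float(mi), 0.0)


def expected_mi(row_margins, col_margins, n: int) -> float:
    """Exact E[MI] under random label permutations with fixed margins.

    Each cell count follows a hypergeometric distribution given (a_i, b_j, n);
    the sum runs over the support max(a_i + b_j - n, 1) .. min(a_i, b_j)
    (the n_ij = 0 term contributes nothing).  Probabilities are evaluated
    through log-factorials.
    """
    a = np.asarray(row_margins, dtype=np.int64)
    b = np.asarray(col_margins, dtype=np.int64)
    if a.sum() != n or b.sum() != n:
        raise ValueError("margins must each sum to n")
    lgn = gammaln(np.arange(n + 2))  # lgn[v + 1] = ln v!
    logfac = lambda v: lgn[np.asarray(v) + 1]
    total = 0.0
    for ai in a:
        for bj in b:
            lo = max(int(ai + bj - n), 1)
            hi = min(int(ai), int(bj))
            if hi < lo:
                continue
            nij = np.arange(lo, hi + 1)
            log_p = (
                logfac(ai)
                + logfac(bj)
                + logfac(n - ai)
                + logfac(n - bj)
                - logfac(n)
                - logfac(nij)
                - logfac(ai - nij)
                - logfac(bj - nij)
                - logfac(n - ai - bj + nij)
            )
            term = nij / n * np.log(n * nij / (float(ai) * float(bj)))
            total += float((term * np.exp(log_p)).sum())
    return total


def _score_from_table(table: ContingencyTable) -> ScoreResult:
    mi = mutual_information(table)
    hx = entropy(table.row_margins, table.n)
    hy = entropy(table.col_margins, table.n)
    max_mi = 0.5 * (hx + hy)
    emi = expected_mi(table.row_margins, table.col_margins, table.n)
    nmi = mi / max_mi if max_mi > 0 else 0.0
    denom = max_mi - emi
    adjusted = (mi - emi) / denom if denom > 1e-15 else 0.0
    return ScoreResult(
        mi=mi,
        nmi=float(np.clip(nmi, 0.0, 1.0)),
        ami=float(adjusted),
        expected_mi=emi,
        max_mi=max_mi,
        n_modules_x=len(table.row_margins),
        n_modules_y=len(table.col_margins),
    )


def ami(x, y) -> ScoreResult:
    """Chance-adjusted mutual information between two aligned partitions.

    Degenerate case: when maxMI - E[MI] vanishes (e.g. both partitions
    constant) no association is detectable and the score is defined as 0.
    """
    return _score_from_table(contingency(x, y))


def conditional_ami(x, y, z) -> ScoreResult:
    """AMI of x and y within strata of z, combined with weights p(z).

    MI, E[MI] and maxMI are each computed per stratum from the
    within-stratum margins and averaged with weights p(z); strata of size 1
    contribute zero to every term.
    """
    x = as_labels(x)
    y = as_labels(y)
    z = as_labels(z)
    if not (x.shape[0] == y.shape[0] == z.shape[0]):
        raise ValueError("partitions must cover the same samples")
    n = x.shape[0]
    if n == 0:
        raise ValueError("empty partitions")
    mi_c = emi_c = hx_c = hy_c = 0.0
    for stratum in np.unique(z):
        mask = z == stratum
        nz = int(mask.sum())
        if nz <= 1:
            continue  # single-sample stratum: all entropies are 0
        w = nz / n
        t = contingency(x[mask], y[mask])
        mi_c += w * mutual_information(t)
        emi_c += w * expected_mi(t.row_margins, t.col_margins, t.n)
        hx_c += w * entropy(t.row_margins, t.n)
        hy_c += w * entropy(t.col_margins, t.n)
    max_mi = 0.5 * (hx_c + hy_c)
    nmi = mi_c / max_mi if max_mi > 0 else 0.0
    denom = max_mi - emi_c
    adjusted = (mi_c - emi_c) / denom if abs(denom) > 1e-15 else 0.0
    return ScoreResult(
        mi=mi_c,
        nmi=float(np.clip(nmi, 0.0, 1.0)),
        ami=float(adjusted),
        expected_mi=emi_c,
        max_mi=max_mi,
        n_modules_x=int(x.max()) + 1,
        n_modules_y=int(y.max()) + 1,
    )


def _observed_and_scorer(x, y, conditional_on):
    if conditional_on is None:
        return ami(x, y).ami, lambda yy: ami(x, yy).ami
    z = as_labels(conditional_on)
    return (
        conditional_ami(x, y, z).ami,
        lambda yy: conditional_ami(x, yy, z).ami,
    )


def permutation_test(
    x,
    y,
    n_perm: int,
    seed: int = 0,
    conditional_on=None,
) -> tuple[float, np.ndarray]:
    """Permutation p-value for the (conditional) AMI of x and y.

    The module partition x stays fixed; phenotype labels y are permuted
    uniformly at random ``n_perm`` times (within confounder strata when
    ``conditional_on`` is given, preserving Pr(Y|Z)).  The p-value uses the
    add-one estimator (1 + #{null >= observed}) / (1 + n_perm), which never
    returns zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = as_labels(x)
    y = as_labels(y)
    rng = np.random.default_rng(seed)
    observed, scorer = _observed_and_scorer(x, y, conditional_on)
    strata = None
    if conditional_on is not None:
        zz = as_labels(conditional_on)
        strata = [np.flatnonzero(zz == s) for s in np.unique(zz)]
    null = np.empty(n_perm)
    perm = y.copy()
    for b in range(n_perm):
        if strata is None:
            perm = rng.permutation(y)
        else:
            for idx in strata:
                perm[idx] = y[idx][rng.permutation(len(idx))]
        null[b] = scorer(perm)
    p = (1 + int((null >= observed - 1e-12).sum())) / (1 + n_perm)
    return float(p), null


def mi_variance(row_margins, col_margins, n: int, limit: int = EXHAUSTIVE_LIMIT) -> float:
    """Var(MI) = E[MI^2] - E[MI]^2 under the permutation null, by enumeration.

    The analytic route through E[MI^2] is numerically difficult, so this is
    an exhaustive small-n oracle (all distinct arrangements of the column
    labels are equiprobable), intended for testing and illustration — use
    :func:`permutation_test` for real data.
    """
    a = np.asarray(row_margins, dtype=np.int64)
    b = np.asarray(col_margins, dtype=np.int64)
    if a.sum() != n or b.sum() != n:
        raise ValueError("margins must each sum to n")
    if n > limit:
        raise ValueError(
            f"exhaustive enumeration limited to n <= {limit}; "
            "use permutation_test for larger problems"
        )
    x = np.repeat(np.arange(len(a)), a)
    y0 = np.repeat(np.arange(len(b)), b)
    mis = [
        mutual_information(contingency(x, np.array(arr)))
        for arr in set(permutations(y0.tolist()))
    ]
    return float(np.var(mis))


def qvalues(p_values, pi0: float | None = None) -> np.ndarray:
    """Storey q-values for a collection of permutation p-values.

    The null proportion pi0 is estimated by smoothing (p > lambda) counts
    over a lambda grid {0.05, ..., 0.95} with a cubic spline evaluated at
    the last grid point; with fewer than 100 p-values the single-point
    estimate at lambda = 0.5 is used instead.  Pass ``pi0`` to override.
    q_i = min over p_j >= p_i of (pi0 * m * p_j / rank_j), clipped to [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if m < 100:
            lam = 0.5
            pi0 = (p > lam).mean() / (1 - lam)
        else:
            from scipy.interpolate import UnivariateSpline

            grid = np.arange(0.05, 0.96, 0.05)
            est = np.array([(p > lam).mean() / (1 - lam) for lam in grid])
            pi0 = float(UnivariateSpline(grid, est, k=3)(grid[-1]))
        pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]  # enforce monotonicity from the tail
    out = np.empty(m)
    out[order] = np.clip(q, 0.0, 1.0)
    return out
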