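import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_mutual_info_score, normalized_mutual_info_score

from mipath import (
    ami,
    as_labels,
    conditional_ami,
    contingency,
    entropy,
    expected_mi,
    mi_variance,
    mutual_information,
    permutation_test,
    qvalues,
)

from oracles import direct_mi, exhaustive_expected_mi, exhaustive_mi_variance

labels_pair = st.integers(2, 30).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(0, 3), min_size=n, max_size=n),
        st.lists(st.integers(0, 3), min_size=n, max_size=n),
    )
)


# ---------------------------------------------------------------- contingency
def test_contingency_examples():
    t = contingency([0, 0, 1, 1], [0, 0, 1, 1])
    np.testing.assert_array_equal(t.counts, [[2, 0], [0, 2]])
    t = contingency([0, 0, 1, 1], [0, 1, 0, 1])
    np.testing.assert_array_equal(t.counts, [[1, 1], [1, 1]])
    t = contingency([0, 0, 0, 0], [0, 1, 0, 1])
    assert t.counts.shape == (1, 2)
    np.testing.assert_array_equal(t.row_margins, [4])
    with pytest.raises(ValueError, match="length mismatch"):
        contingency([0, 1], [0, 1, 0])


# --------------------------------------------------------- mutual information
def test_mi_identical_two_group_partition_is_ln2():
    t = contingency([0, 0, 1, 1], [0, 0, 1, 1])
    assert mutual_information(t) == pytest.approx(np.log(2), abs=1e-12)


def test_mi_constant_partition_is_zero():
    t = contingency([0, 0, 0, 0], [0, 1, 2, 1])
    assert mutual_information(t) == 0.0


def test_mi_matches_direct_summation():
    t = contingency([0, 0, 0, 1, 1, 1], [0, 0, 1, 1, 1, 1])
    np.testing.assert_array_equal(t.counts, [[2, 1], [0, 3]])
    # 0.3182570841474064 from the independent direct-sum oracle
    assert mutual_information(t) == pytest.approx(direct_mi([[2, 1], [0, 3]]), abs=1e-12)
    assert mutual_information(t) == pytest.approx(0.3182570841474064, abs=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(labels_pair)
def test_mi_entropy_form_identity(pair):
    """MI equals H(X) + H(Y) - H(X,Y) computed from the same table."""
    x, y = pair
    t = contingency(x, y)
    hx = entropy(t.row_margins, t.n)
    hy = entropy(t.col_margins, t.n)
    hxy = entropy(t.counts.ravel(), t.n)
    assert mutual_information(t) == pytest.approx(hx + hy - hxy, abs=1e-12)


# ----------------------------------------------------------------- expected MI
def test_expected_mi_constant_partition_is_zero():
    assert expected_mi([6], [3, 2, 1], 6) == pytest.approx(0.0, abs=1e-15)


@pytest.mark.parametrize(
    "a,b",
    [((2, 2), (2, 2)), ((3, 2, 1), (2, 2, 2)), ((4, 1), (3, 2)), ((2, 2, 2, 2), (5, 3))],
)
def test_expected_mi_matches_exhaustive_oracle(a, b):
    n = sum(a)
    assert expected_mi(a, b, n) == pytest.approx(exhaustive_expected_mi(a, b), abs=1e-10)


def test_expected_mi_margin_mismatch_rejected():
    with pytest.raises(ValueError, match="sum to n"):
        expected_mi([2, 2], [3, 2], 4)


# ------------------------------------------------------------------------ AMI
def test_ami_of_partition_with_itself_is_one():
    x = [0, 0, 0, 0, 0, 1, 1, 1, 2, 2]
    assert ami(x, x).ami == pytest.approx(1.0, abs=1e-12)


def test_ami_degenerate_constant_partitions():
    r = ami([0, 0, 0], [1, 1, 1])
    assert r.ami == 0.0 and r.nmi == 0.0 and r.mi == 0.0


def test_ami_three_by_two_example_matches_oracle_pieces():
    x = [0, 0, 1, 1, 2, 2]
    y = [0, 0, 0, 1, 1, 1]
    r = ami(x, y)
    # all three pieces computed independently: MI by direct summation,
    # E[MI] by exhaustive permutation, maxMI from the margin entropies
    assert r.mi == pytest.approx(0.46209812037329684, abs=1e-12)
    assert r.expected_mi == pytest.approx(0.27725887222397816, abs=1e-10)
    assert r.max_mi == pytest.approx(0.8958797346140275, abs=1e-12)
    assert r.ami == pytest.approx(0.29879245817088995, abs=1e-9)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(labels_pair)
def test_ami_symmetry_relabeling_and_bounds(pair):
    x, y = pair
    r = ami(x, y)
    assert 0.0 <= r.nmi <= 1.0
    assert r.ami <= 1.0 + 1e-12
    assert r.ami == pytest.approx(ami(y, x).ami, abs=1e-10)
    relabeled = [5 - v for v in x]  # bijective relabeling
    assert r.ami == pytest.approx(ami(relabeled, y).ami, abs=1e-10)


def test_ami_agrees_with_sklearn(rng):
    """Cross-check against an established independent implementation."""
    for _ in range(20):
        n = rng.integers(10, 200)
        x = rng.integers(0, rng.integers(2, 6), n)
        y = rng.integers(0, rng.integers(2, 6), n)
        assert ami(x, y).ami == pytest.approx(
            adjusted_mutual_info_score(x, y, average_method="arithmetic"), abs=1e-9
        )
        assert ami(x, y).nmi == pytest.approx(
            normalized_mutual_info_score(x, y, average_method="arithmetic"), abs=1e-9
        )


def test_ami_identical_iff_one_nondegenerate(rng):
    x = rng.integers(0, 3, 60)
    assert ami(x, x).ami == pytest.approx(1.0, abs=1e-12)
    y = x.copy()
    y[:5] = (y[:5] + 1) % 3
    assert ami(x, y).ami < 1.0


def test_ami_mean_near_zero_for_independent_partitions(rng):
    vals = [
        ami(rng.integers(0, 4, 100), rng.integers(0, 4, 100)).ami for _ in range(1000)
    ]
    assert abs(np.mean(vals)) <= 0.01


# ---------------------------------------------------------------- conditional
def test_conditional_with_constant_z_equals_unconditional(rng):
    x = rng.integers(0, 3, 40)
    y = rng.integers(0, 2, 40)
    r1 = conditional_ami(x, y, np.zeros(40, dtype=int))
    r2 = ami(x, y)
    assert r1.ami == pytest.approx(r2.ami, abs=1e-12)
    assert r1.mi == pytest.approx(r2.mi, abs=1e-12)
    assert r1.expected_mi == pytest.approx(r2.expected_mi, abs=1e-12)


def test_conditional_on_perfect_confounder(rng):
    """Z == X: H(X|Z) = 0, within-stratum MI = 0, score <= 0 (or 0)."""
    x = rng.integers(0, 3, 60)
    y = rng.integers(0, 2, 60)
    r = conditional_ami(x, y, x)
    assert r.mi == pytest.approx(0.0, abs=1e-12)
    assert r.ami <= 1e-12


def test_conditional_two_strata_weighted_combination():
    """Strata of sizes 4 and 6 combine per-stratum oracle values with p(z)."""
    x = np.array([0, 0, 1, 1, 0, 0, 0, 1, 1, 1])
    y = np.array([0, 1, 0, 1, 0, 0, 1, 1, 1, 0])
    z = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
    r = conditional_ami(x, y, z)
    mi_parts, emi_parts, hx_parts, hy_parts = [], [], [], []
    for s, w in [(0, 0.4), (1, 0.6)]:
        t = contingency(x[z == s], y[z == s])
        mi_parts.append(w * direct_mi(t.counts))
        emi_parts.append(w * exhaustive_expected_mi(t.row_margins, t.col_margins))
        hx_parts.append(w * entropy(t.row_margins, t.n))
        hy_parts.append(w * entropy(t.col_margins, t.n))
    mi_c, emi_c = sum(mi_parts), sum(emi_parts)
    max_c = 0.5 * (sum(hx_parts) + sum(hy_parts))
    assert r.mi == pytest.approx(mi_c, abs=1e-12)
    assert r.expected_mi == pytest.approx(emi_c, abs=1e-10)
    assert r.ami == pytest.approx((mi_c - emi_c) / (max_c - emi_c), abs=1e-9)


def test_conditional_singleton_strata_contribute_zero(rng):
    x = np.array([0, 1, 0, 1, 1])
    y = np.array([0, 0, 1, 1, 0])
    z = np.array([0, 0, 0, 0, 1])  # one singleton stratum
    r = conditional_ami(x, y, z)
    t = contingency(x[:4], y[:4])
    assert r.mi == pytest.approx(0.8 * mutual_information(t), abs=1e-12)


# ---------------------------------------------------------------- permutation
def test_permutation_p_floor_when_observed_beats_all(rng):
    x = np.repeat([0, 1, 2], 20)
    p, null = permutation_test(x, x, n_perm=99, seed=0)
    assert p == pytest.approx(1 / 100)
    assert len(null) == 99 and null.max() < 1.0


def test_permutation_deterministic_under_seed(rng):
    x = rng.integers(0, 3, 50)
    y = rng.integers(0, 2, 50)
    p1, n1 = permutation_test(x, y, n_perm=50, seed=42)
    p2, n2 = permutation_test(x, y, n_perm=50, seed=42)
    assert p1 == p2
    np.testing.assert_array_equal(n1, n2)


def test_conditional_permutation_preserves_strata(rng):
    """Within-stratum phenotype margins are a permutation invariant."""
    x = rng.integers(0, 3, 40)
    z = np.repeat([0, 1], 20)
    y = rng.integers(0, 2, 40)
    p, null = permutation_test(x, y, n_perm=30, seed=1, conditional_on=z)
    assert 0 < p <= 1 and len(null) == 30
    # p-value floor for a strong within-stratum association
    p2, _ = permutation_test(x, x, n_perm=99, seed=1, conditional_on=z)
    assert p2 == pytest.approx(1 / 100)


# ------------------------------------------------------------------- variance
def test_mi_variance_constant_is_zero():
    assert mi_variance([4], [2, 2], 4) == 0.0


def test_mi_variance_matches_exhaustive_oracle():
    v = mi_variance([2, 2], [2, 2], 4)
    assert v == pytest.approx(exhaustive_mi_variance([2, 2], [2, 2]), abs=1e-12)
    assert v == pytest.approx(0.106767336426267, abs=1e-10)
    assert v >= 0


def test_mi_variance_refuses_large_n():
    with pytest.raises(ValueError, match="permutation_test"):
        mi_variance([30, 30], [30, 30], 60)


# ------------------------------------------------------------------- q-values
def test_qvalues_all_ones():
    np.testing.assert_allclose(qvalues([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])


def test_qvalues_step_up_hand_example():
    p = np.array([0.001] * 10 + [0.9] * 90)
    q = qvalues(p, pi0=1.0)
    np.testing.assert_allclose(q[:10], 0.01)  # 0.001 * 100 / 10
    np.testing.assert_allclose(q[10:], 0.9)  # 0.9 * 100 / 100


def test_qvalues_monotone_in_p(rng):
    p = rng.random(500)
    q = qvalues(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)
    assert np.all((q >= 0) & (q <= 1))


def test_qvalues_empty_and_bounds():
    assert qvalues([]).size == 0
    with pytest.raises(ValueError):
        qvalues([0.5, 1.5])


def test_as_labels_encoding():
    np.testing.assert_array_equal(as_labels(["b", "a", "b", "c"]), [1, 0, 1, 2])
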