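"""Mk(1) transition probabilities, pruning likelihood, marginal ancestral
probabilities and rate estimation."""

import math

import numpy as np
import pytest
import scipy.linalg

from morphostrat import (
    CharacterMatrix,
    MkModel,
    ValidationError,
    mk_fit_rate,
    mk_loglik,
    mk_marginal,
    mk_transition,
    simulate_mk_matrix,
    simulate_yule_tree,
)
from conftest import tree_from_newick


def rate_matrix(model: MkModel) -> np.ndarray:
    Q = np.full((model.k, model.k), model.beta)
    np.fill_diagonal(Q, -(model.k - 1) * model.beta)
    return Q


class TestTransition:
    @pytest.mark.parametrize("k", [2, 3, 4, 6])
    @pytest.mark.parametrize("t", [0.01, 0.5, 1.3, 7.0])
    def test_matches_matrix_exponential(self, k, t):
        model = MkModel(k=k, rate=0.7)
        P = mk_transition(model, t)
        expected = scipy.linalg.expm(rate_matrix(model) * t)
        assert np.abs(P - expected).max() < 1e-10

    def test_zero_branch_is_identity(self):
        assert np.allclose(mk_transition(MkModel(k=4), 0.0), np.eye(4))

    def test_long_branch_reaches_stationarity(self):
        model = MkModel(k=3, rate=1.0)
        P = mk_transition(model, 1e6)
        assert np.abs(P - 1 / 3).max() < 1e-9

    def test_two_state_closed_form(self):
        # beta = 0.5 for k=2 means total rate r = 0.5
        model = MkModel(k=2, rate=0.5)
        P = mk_transition(model, 1.0)
        assert P[0, 0] == pytest.approx(0.5 + 0.5 * math.exp(-1.0))

    def test_rows_sum_to_one(self):
        P = mk_transition(MkModel(k=5, rate=2.0), 0.37)
        assert np.abs(P.sum(axis=1) - 1).max() < 1e-12

    def test_negative_branch_rejected(self):
        with pytest.raises(ValidationError):
            mk_transition(MkModel(k=2), -0.1)


class TestLoglik:
    def test_zero_branches_point_mass(self):
        tree = tree_from_newick("(A:0,B:0);")
        m = CharacterMatrix.from_states(["A", "B"], [[0], [0]])
        ll = mk_loglik(tree, m, 0, MkModel(k=3, rate=1.0))
        assert ll == pytest.approx(math.log(1 / 3))

    def test_all_missing_likelihood_one(self):
        tree = tree_from_newick("(A:1,B:2);")
        m = CharacterMatrix.from_states(["A", "B"], [[None], [None]])
        # a single-state degenerate alphabet still needs k >= 2
        assert mk_loglik(tree, m, 0, MkModel(k=2, rate=1.0)) == pytest.approx(0.0)

    def test_two_tip_brute_force(self):
        t1, t2 = 0.4, 1.1
        tree = tree_from_newick(f"(A:{t1},B:{t2});")
        m = CharacterMatrix.from_states(["A", "B"], [[0], [1]])
        model = MkModel(k=2, rate=0.8)
        P1, P2 = mk_transition(model, t1), mk_transition(model, t2)
        expected = sum(0.5 * P1[s, 0] * P2[s, 1] for s in range(2))
        assert mk_loglik(tree, m, 0, model) == pytest.approx(math.log(expected))

    def test_missing_tip_does_not_alter_remaining_data(self):
        # (0, ?) two-tip likelihood equals the stationary 1/k of the scored tip
        tree = tree_from_newick("(A:0.7,B:1.9);")
        m = CharacterMatrix.from_states(["A", "B"], [[0], [None]])
        ll = mk_loglik(tree, m, 0, MkModel(k=4, rate=0.6))
        assert ll == pytest.approx(math.log(1 / 4))

    def test_unscored_tip_rejected(self):
        tree = tree_from_newick("(A:1,X:1);")
        m = CharacterMatrix.from_states(["A", "B"], [[0], [1]])
        with pytest.raises(ValidationError, match="X"):
            mk_loglik(tree, m, 0, MkModel(k=2))

    @pytest.mark.parametrize(
        "rooting_a, rooting_b",
        [
            ("((A:1,B:2):0.5,(C:1.5,D:0.5):0.5);", "(A:1,(B:2,((C:1.5,D:0.5):1):0):0);"),
            ("((A:1,B:2):0.5,(C:1.5,D:0.5):0.5);", "(C:1.5,(D:0.5,((A:1,B:2):1):0):0);"),
        ],
    )
    def test_rerooting_invariance(self, rooting_a, rooting_b):
        # same unrooted tree with identical edge lengths, rooted differently
        m = CharacterMatrix.from_states(["A", "B", "C", "D"], [[0], [1], [0], [1]])
        model = MkModel(k=2, rate=0.9)
        la = mk_loglik(tree_from_newick(rooting_a), m, 0, model)
        lb = mk_loglik(tree_from_newick(rooting_b), m, 0, model)
        assert la == pytest.approx(lb, abs=1e-12)


class TestMarginal:
    def test_symmetric_cherries_ambiguous_root(self):
        tree = tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        m = CharacterMatrix.from_states(["A", "B", "C", "D"], [[0], [0], [1], [1]])
        post = mk_marginal(tree, m, 0, MkModel(k=2, rate=0.5))
        root_vec = post[tree.root]
        assert root_vec[0] == pytest.approx(0.5)

    def test_uniform_signal_confident_root(self):
        tree = tree_from_newick("((A:0.01,B:0.01):0.01,(C:0.01,D:0.01):0.01);")
        m = CharacterMatrix.from_states(["A", "B", "C", "D"], [[0], [0], [0], [0]])
        post = mk_marginal(tree, m, 0, MkModel(k=2, rate=1.0))
        assert post[tree.root][0] > 0.99

    def test_huge_rate_goes_stationary(self):
        tree = tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        m = CharacterMatrix.from_states(["A", "B", "C", "D"], [[0], [0], [0], [1]])
        post = mk_marginal(tree, m, 0, MkModel(k=2, rate=1e4))
        for node, vec in post.items():
            if not node.is_tip:
                assert np.abs(vec - 0.5).max() < 1e-3

    def test_vectors_sum_to_one(self):
        ts, _ = simulate_yule_tree(12, 0.5, seed=3)
        matrix, _ = simulate_mk_matrix(ts, 5, 3, rate=0.4, seed=4)
        post = mk_marginal(ts, matrix, 2, MkModel(k=3, rate=0.4))
        for vec in post.values():
            assert abs(vec.sum() - 1.0) < 1e-10


class TestFitRate:
    def test_doubling_lengths_halves_rate(self):
        ts, _ = simulate_yule_tree(16, 0.5, seed=9)
        matrix, _ = simulate_mk_matrix(ts, 120, 2, rate=0.6, seed=10)
        r1, _ = mk_fit_rate(ts, matrix)
        doubled = ts.copy()
        for node in doubled.postorder():
            if node.length is not None:
                node.length *= 2
        r2, _ = mk_fit_rate(doubled, matrix)
        assert r2 == pytest.approx(r1 / 2, rel=1e-3)

    def test_constant_data_hits_lower_bound(self):
        tree = tree_from_newick("((A:1,B:1):1,C:2);")
        m = CharacterMatrix.from_states(["A", "B", "C"], [[0, 0], [0, 0], [0, 0]])
        with pytest.warns(UserWarning, match="constant"):
            r, _ = mk_fit_rate(tree, m, k=2)
        assert r <= 1e-6

    def test_recovers_simulated_rate(self):
        ts, _ = simulate_yule_tree(64, 0.5, seed=21)
        matrix, _ = simulate_mk_matrix(ts, 300, 3, rate=0.5, seed=22)
        r, _ = mk_fit_rate(ts, matrix)
        assert abs(r - 0.5) / 0.5 < 0.2


# ---------------------------------------------------------------------------
# hypothesis property tests

from hypothesis import given, settings, strategies as st


@settings(max_examples=80, derandomize=True)
@given(
    st.integers(min_value=2, max_value=8),
    st.floats(min_value=0.0, max_value=50.0, allow_nan=False),
    st.floats(min_value=1e-3, max_value=10.0, allow_nan=False),
)
def test_transition_is_stochastic_and_symmetric(k, t, rate):
    """Rows sum to 1, entries are probabilities, and the matrix is symmetric
    (uniform exchangeabilities) for any k, t, rate."""
    P = mk_transition(MkModel(k=k, rate=rate), t)
    assert np.abs(P.sum(axis=1) - 1).max() < 1e-9
    assert (P >= -1e-15).all() and (P <= 1 + 1e-12).all()
    assert np.abs(P - P.T).max() < 1e-12


@settings(max_examples=50, derandomize=True)
@given(
    st.integers(min_value=2, max_value=6),
    st.floats(min_value=1e-3, max_value=5.0),
    st.floats(min_value=1e-3, max_value=5.0),
)
def test_transition_semigroup_property(k, t1, t2):
    """P(t1) @ P(t2) == P(t1 + t2): the closed form is a true Markov
    semigroup."""
    model = MkModel(k=k, rate=0.7)
    lhs = mk_transition(model, t1) @ mk_transition(model, t2)
    rhs = mk_transition(model, t1 + t2)
    assert np.abs(lhs - rhs).max() < 1e-10
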