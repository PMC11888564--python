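import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import netpattern as npt
from netpattern.network import NetworkError


VPC_ADJACENCY = np.array(
    [
        [0, 2, 0, 0, 0, 0],
        [1, 0, 1, 0, 0, 0],
        [0, 1, 0, 1, 0, 0],
        [0, 0, 1, 0, 1, 0],
        [0, 0, 0, 1, 0, 1],
        [0, 0, 0, 0, 2, 0],
    ]
)


class TestReflectiveRow:
    def test_six_cell_vulva_adjacency(self, vpc):
        assert np.array_equal(npt.adjacency_matrix(vpc), VPC_ADJACENCY)

    @pytest.mark.parametrize(
        "n,weight,expected",
        [
            (2, 1, [[0, 2], [2, 0]]),
            (3, 1, [[0, 2, 0], [1, 0, 1], [0, 2, 0]]),
        ],
    )
    def test_small_rows(self, n, weight, expected):
        net = npt.build_reflective_row(n, weight)
        assert np.array_equal(npt.adjacency_matrix(net), np.array(expected))

    def test_too_small(self):
        with pytest.raises(NetworkError):
            npt.build_reflective_row(1, 1)


class TestTorusLattice:
    def test_periodic_ring(self):
        net = npt.build_torus_lattice(1, 3, {(0, -1): 1, (0, 1): 1})
        expected = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        assert np.array_equal(npt.adjacency_matrix(net), expected)

    def test_wrap_rule(self):
        net = npt.build_torus_lattice(2, 2, {(0, 1): 1})
        A = npt.adjacency_matrix(net)
        assert net.valence == 1
        # cell (r, c) receives from (r, c+1 mod 2); row-major order
        assert A[0, 1] == 1 and A[1, 0] == 1 and A[2, 3] == 1 and A[3, 2] == 1

    def test_notch_lattice_size_and_valence(self):
        net = npt.build_torus_lattice(16, 16, npt.notch_lattice_stencil())
        assert net.n_nodes == 256
        assert net.valence == 16  # 4 nearest at 3 plus 4 diagonal at 1

    def test_self_arrow_offset_rejected(self):
        with pytest.raises(NetworkError):
            npt.build_torus_lattice(2, 2, {(0, 0): 1})
        with pytest.raises(NetworkError):
            npt.build_torus_lattice(2, 2, {(2, 0): 1})  # wraps onto itself

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(NetworkError):
            npt.build_torus_lattice(2, 2, {(0, 1): 0})


@settings(deadline=None, max_examples=40)
@given(
    n=st.integers(2, 10),
    weight=st.integers(1, 3),
)
def test_constructed_adjacency_is_regular_with_zero_diagonal(n, weight):
    net = npt.build_reflective_row(n, weight)
    A = npt.adjacency_matrix(net)
    assert np.all(A.sum(axis=1) == 2 * weight)
    assert np.all(np.diag(A) == 0)


@settings(deadline=None, max_examples=30)
@given(
    rows=st.integers(1, 4),
    cols=st.integers(2, 4),
    w1=st.integers(1, 3),
    w2=st.integers(1, 3),
)
def test_torus_adjacency_is_regular_with_zero_diagonal(rows, cols, w1, w2):
    net = npt.build_torus_lattice(rows, cols, {(0, 1): w1, (0, -1): w2})
    A = npt.adjacency_matrix(net)
    assert np.all(A.sum(axis=1) == A.sum(axis=1)[0])
    assert np.all(np.diag(A) == 0)


class TestValidate:
    def test_vpc_report(self, vpc):
        rep = npt.validate_network(vpc)
        assert rep["valence"] == 2
        assert rep["is_regular"] and rep["is_strongly_connected"]
        assert not rep["has_self_arrows"]

    def test_one_way_chain(self):
        A = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        net = npt.RegularNetwork.from_adjacency(A, strict=False)
        rep = npt.validate_network(net)
        assert not rep["is_strongly_connected"]
        assert not rep["is_regular"]
        assert rep["input_counts"] == [0, 1, 1]

    def test_symmetric_torus_strongly_connected(self, lattice8):
        assert npt.validate_network(lattice8)["is_strongly_connected"]

    def test_single_node_vacuously_connected(self):
        net = npt.RegularNetwork.from_adjacency(np.zeros((1, 1), int), strict=False)
        assert npt.validate_network(net)["is_strongly_connected"]


class TestBalancedColorings:
    def test_vpc_alternating_is_balanced(self, vpc):
        assert npt.is_balanced(vpc, npt.Coloring((1, 2, 1, 2, 1, 2)))

    def test_vpc_blockwise_is_not_balanced(self, vpc):
        assert not npt.is_balanced(vpc, npt.Coloring((1, 1, 2, 2, 2, 2)))

    def test_size_mismatch(self, vpc):
        with pytest.raises(NetworkError):
            npt.is_balanced(vpc, npt.Coloring((1, 2)))

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_single_color_always_balanced(self, seed):
        from netpattern.validate import random_regular_network

        net = random_regular_network(np.random.default_rng(seed), n_max=12)
        assert npt.is_balanced(net, npt.Coloring((1,) * net.n_nodes))


class TestPolysynchronyBasis:
    @pytest.mark.parametrize(
        "colors,expected",
        [
            ((1, 2, 1, 2), [[1, 0, 1, 0], [0, 1, 0, 1]]),
            ((1, 2, 2, 1), [[1, 0, 0, 1], [0, 1, 1, 0]]),
            ((1, 1, 1), [[1, 1, 1]]),
        ],
    )
    def test_indicator_spans(self, colors, expected):
        basis = npt.polysynchrony_basis(npt.Coloring(colors), node_dim=1)
        assert np.array_equal(basis, np.array(expected, dtype=float))

    def test_dimension_and_independence(self):
        col = npt.Coloring((1, 2, 3, 2, 1))
        basis = npt.polysynchrony_basis(col, node_dim=2)
        assert basis.shape == (6, 10)
        assert np.linalg.matrix_rank(basis) == 6

    def test_vectors_lie_in_subspace(self):
        # each basis vector is constant within colors by construction
        col = npt.Coloring((1, 2, 1))
        basis = npt.polysynchrony_basis(col, node_dim=2)
        colors = np.array(col.assignment)
        for vec in basis:
            per_node = vec.reshape(3, 2)
            for c in (1, 2):
                rows = per_node[colors == c]
                assert np.all(rows == rows[0])


class TestColoringFromPattern:
    def test_alternating(self):
        col = npt.coloring_from_pattern_vector([1, -1, 1, -1, 1, -1])
        assert col.assignment == (1, 2, 1, 2, 1, 2)

    def test_constant(self):
        assert npt.coloring_from_pattern_vector([3.3] * 5).assignment == (1,) * 5

    def test_exact_grouping(self):
        assert npt.coloring_from_pattern_vector([1.0, 0.5, 1.0]).assignment == (1, 2, 1)

    def test_colors_ordered_by_decreasing_value(self):
        col = npt.coloring_from_pattern_vector([0.0, 2.0, -1.0])
        assert col.assignment == (2, 1, 3)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000))
    def test_recovers_refinement_of_balanced_coloring(self, seed, vpc):
        rng = np.random.default_rng(seed)
        col = npt.Coloring((1, 2, 1, 2, 1, 2))
        values = rng.normal(size=col.k)
        v = np.array([values[c - 1] for c in col.assignment])
        rec = npt.coloring_from_pattern_vector(v)
        # recovered coloring must refine (or equal) the generating one:
        # nodes sharing a recovered color share the generating color
        for c in range(1, rec.k + 1):
            nodes = [i for i, ci in enumerate(rec.assignment) if ci == c]
            gen = {col.assignment[i] for i in nodes}
            assert len(gen) == 1
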