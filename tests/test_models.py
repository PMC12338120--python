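"""GCN member, GPCN ensemble, and baseline model forwards against oracles."""

import numpy as np
import pytest

from gpcn import autodiff as ad
from gpcn.autodiff import Var
from gpcn.models import (
    AuxGCN,
    GPCNModel,
    Member,
    MemberSpec,
    diffpool_coarsen,
    gcn_forward,
    member_forward,
    ngcn_forward,
)
from gpcn.tube_graphs import TubeSpec, build_tube_graph, laplacian


def np_member_forward(Z, X, member):
    """Independent dense-arithmetic oracle for the member architecture."""
    Z = np.asarray(Z)
    H = np.asarray(X)
    outs = []
    for W, b in zip(member.gcn_W, member.gcn_b):
        H = np.maximum(Z @ H @ W.value + b.value, 0.0)
        outs.append(H)
    D = np.concatenate(outs, axis=-1)
    n_dense = len(member.dense_W)
    for i, (W, b) in enumerate(zip(member.dense_W, member.dense_b)):
        D = D @ W.value + b.value
        if i < n_dense - 1:
            D = 1.0 / (1.0 + np.exp(-D))
    return D


@pytest.fixture
def small_Z():
    return laplacian(build_tube_graph(TubeSpec(1, 5, 0)), dense=True)  # 5 nodes


class TestGCNForward:
    def test_zero_weights_relu_gives_zero(self, small_Z):
        X = np.ones((5, 3))
        layers = [(np.zeros((3, 4)), np.zeros(4))]
        assert np.all(gcn_forward(small_Z, X, layers) == 0.0)

    def test_zero_structure_linear_gives_bias(self):
        X = np.ones((4, 2))
        b = np.array([1.5, -2.0])
        out = gcn_forward(np.zeros((4, 4)), X, [(np.ones((2, 2)), b)], activation="linear")
        assert np.allclose(out, np.tile(b, (4, 1)))

    def test_matches_dense_arithmetic_oracle(self, small_Z):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((5, 3))
        W, b = rng.standard_normal((3, 4)), rng.standard_normal(4)
        got = gcn_forward(small_Z, X, [(W, b)])
        assert np.allclose(got, np.maximum(small_Z @ X @ W + b, 0.0))


class TestMemberForward:
    def test_dense_head_consumes_concatenated_gcn_outputs(self):
        member = Member(MemberSpec(0, (3, 5), (4, 1)), 2, np.random.default_rng(0))
        assert member.dense_W[0].shape == (8, 4)  # 3 + 5 concatenated filters

    def test_zero_dense_weights_output_is_final_bias(self, small_Z):
        rng = np.random.default_rng(1)
        member = Member(MemberSpec(0, (3,), (1,)), 2, rng)
        member.dense_W[0].value[:] = 0.0
        member.dense_b[0].value[:] = 4.5
        out = member_forward(small_Z, rng.standard_normal((5, 2)), member)
        assert np.allclose(out, 4.5)

    def test_matches_oracle(self, small_Z):
        rng = np.random.default_rng(2)
        member = Member(MemberSpec(0, (4, 4), (6, 1)), 3, rng)
        X = rng.standard_normal((5, 3))
        assert np.allclose(
            member_forward(small_Z, X, member),
            np_member_forward(small_Z, X, member),
            rtol=1e-12,
        )


class TestGPCNForward:
    def test_sum_of_parts_oracle(self, toy_gpcn):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((12, 3))
        Z1 = toy_gpcn.structure_matrices[0].value
        Z2 = toy_gpcn.structure_matrices[1].value
        P = toy_gpcn.projections[0].value
        expected = np_member_forward(Z1, X, toy_gpcn.members[0]) + P @ np_member_forward(
            Z2, P.T @ X, toy_gpcn.members[1]
        )
        assert np.allclose(toy_gpcn.predict(X), expected, rtol=1e-10)

    def test_zeroed_coarse_member_reduces_to_fine(self, toy_hierarchy):
        rng = np.random.default_rng(4)
        specs = [MemberSpec(0, (4,), (3, 1)), MemberSpec(1, (4,), (3, 1))]
        model = GPCNModel(toy_hierarchy, specs, in_features=2, rng=rng)
        for var in model.members[1].dense_W + model.members[1].dense_b:
            var.value[:] = 0.0
        X = rng.standard_normal((12, 2))
        fine_only = np_member_forward(model.structure_matrices[0].value, X, model.members[0])
        assert np.allclose(model.predict(X), fine_only)

    def test_member_linearity(self, toy_gpcn):
        """Doubling a member's linear output layer doubles its contribution."""
        rng = np.random.default_rng(5)
        X = rng.standard_normal((12, 3))
        base = toy_gpcn.predict(X)
        m = toy_gpcn.members[1]
        P = toy_gpcn.projections[0].value
        contrib = P @ np_member_forward(toy_gpcn.structure_matrices[1].value, P.T @ X, m)
        m.dense_W[-1].value *= 2.0
        m.dense_b[-1].value *= 2.0
        doubled = toy_gpcn.predict(X)
        m.dense_W[-1].value /= 2.0
        m.dense_b[-1].value /= 2.0
        assert np.allclose(doubled - base, contrib, rtol=1e-9, atol=1e-12)

    def test_batched_forward_matches_per_sample(self, toy_gpcn):
        rng = np.random.default_rng(6)
        Xb = rng.standard_normal((4, 12, 3))
        got = toy_gpcn.forward(Var(Xb, requires_grad=False)).value
        for i in range(4):
            assert np.array_equal(got[i], toy_gpcn.predict(Xb[i]))

    def test_adaptive_projections_receive_gradients(self, toy_hierarchy):
        specs = [MemberSpec(0, (4,), (3, 1)), MemberSpec(1, (4,), (3, 1))]
        model = GPCNModel(toy_hierarchy, specs, in_features=2, adaptive=True,
                          rng=np.random.default_rng(8))
        rng = np.random.default_rng(9)
        X = rng.standard_normal((12, 2))
        y = rng.standard_normal((12, 1))
        loss = ad.mean_square_error(model.forward(Var(X, requires_grad=False)), y)
        ad.backward(loss)
        assert model.projections[0].grad is not None
        assert np.abs(model.projections[0].grad).max() > 0

    def test_static_projections_hold_no_gradient(self, toy_gpcn):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((12, 3))
        for p in toy_gpcn.parameters():
            p.grad = None
        toy_gpcn.projections[0].grad = None
        loss = ad.mean_square_error(
            toy_gpcn.forward(Var(X, requires_grad=False)), np.zeros((12, 1))
        )
        ad.backward(loss)
        assert toy_gpcn.projections[0].grad is None


class TestNGCN:
    def test_single_radius_is_plain_gcn(self, small_Z):
        rng = np.random.default_rng(11)
        member = Member(MemberSpec(0, (4,), (3, 1)), 2, rng)
        X = rng.standard_normal((5, 2))
        got = ngcn_forward(small_Z, X, (1,), [member])
        assert np.allclose(got, np_member_forward(small_Z, X, member))

    def test_power_radius_uses_matrix_power(self, small_Z):
        rng = np.random.default_rng(12)
        member = Member(MemberSpec(0, (4,), (3, 1)), 2, rng)
        X = rng.standard_normal((5, 2))
        got = ngcn_forward(small_Z, X, (2,), [member])
        assert np.allclose(got, np_member_forward(small_Z @ small_Z, X, member))


class TestDiffPool:
    def test_rows_on_simplex_and_shapes(self, small_Z):
        rng = np.random.default_rng(13)
        aux = AuxGCN((4, 3), 2, rng)
        X = rng.standard_normal((5, 2))
        Zc, Xc, S = diffpool_coarsen(small_Z, X, aux)
        assert S.shape == (5, 3) and Zc.shape == (3, 3) and Xc.shape == (3, 2)
        assert np.allclose(S.sum(axis=-1), 1.0)
        assert np.all(S >= 0)

    def test_hard_partition_matches_block_sum_oracle(self, small_Z):
        """Saturated assignments reduce S^T Z S to block aggregation."""
        rng = np.random.default_rng(14)
        aux = AuxGCN((2,), 1, rng)
        # force near-one-hot rows: huge last-layer bias pattern
        aux.W[0].value[:] = 0.0
        aux.b[0].value[:] = [1000.0, 0.0]
        X = np.ones((5, 1))
        Zc, Xc, S = diffpool_coarsen(small_Z, X, aux)
        hard = np.zeros((5, 2))
        hard[:, 0] = 1.0  # every node assigned to cluster 0
        assert np.allclose(S, hard, atol=1e-12)
        assert np.allclose(Zc, hard.T @ small_Z @ hard)
        assert np.allclose(Xc, hard.T @ X)

    def test_pooling_must_shrink(self, small_Z):
        aux = AuxGCN((6,), 2, np.random.default_rng(15))
        with pytest.raises(ValueError):
            diffpool_coarsen(small_Z, np.ones((5, 2)), aux)
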