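"""Two-view contrastive pre-training: augmentation, encoding, loss, EMA."""

import numpy as np
import pytest

from _oracles import gcn_forward_dense
from dtifuse.contrastive import (ContrastiveView, GCNEncoder, Predictor,
                                 augment, contrastive_loss, ema_update,
                                 extract_relational_features,
                                 normalized_adjacency, train_gcl)
from dtifuse.relational import RelationalNetwork
from dtifuse import autograd as ag


def _random_network(n, p_edge, dim=12, seed=0):
    rng = np.random.default_rng(seed)
    A = (rng.random((n, n)) < p_edge).astype(np.int8)
    A = np.triu(A, 1)
    A = A + A.T
    X = rng.standard_normal((n, dim))
    return RelationalNetwork(A=A, X=X, entity="drug")


def _two_block_network(n=40, p_in=0.5, p_out=0.02, dim=16, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    blocks = np.array([0] * half + [1] * (n - half))
    P = np.where(blocks[:, None] == blocks[None, :], p_in, p_out)
    A = (rng.random((n, n)) < P).astype(np.int8)
    A = np.triu(A, 1)
    A = A + A.T
    X = rng.standard_normal((n, dim))
    return RelationalNetwork(A=A, X=X, entity="drug"), blocks


class TestAugment:
    def test_identity_when_probs_zero(self):
        net = _random_network(12, 0.4)
        v = augment(net, 0.0, 0.0, seed=1)
        assert np.array_equal(v.A, net.A)
        assert np.array_equal(v.X, net.X)

    def test_edges_only_removed_and_rows_zeroed(self):
        net = _random_network(30, 0.5, seed=2)
        v = augment(net, 0.5, 0.5, seed=3)
        assert ((net.A - v.A) >= 0).all()          # subset of original edges
        assert np.array_equal(v.A, v.A.T)
        zero_rows = ~v.X.any(axis=1)
        assert zero_rows.sum() > 0
        kept = ~zero_rows
        assert np.array_equal(v.X[kept], net.X[kept])

    def test_deterministic_given_seed(self):
        net = _random_network(20, 0.4, seed=4)
        a = augment(net, 0.3, 0.3, seed=7)
        b = augment(net, 0.3, 0.3, seed=7)
        assert np.array_equal(a.A, b.A) and np.array_equal(a.X, b.X)

    def test_invalid_probability(self):
        net = _random_network(5, 0.5)
        with pytest.raises(ValueError):
            augment(net, 1.0, 0.0, seed=0)


class TestEncoder:
    def test_matches_dense_oracle_small_graph(self):
        net = _random_network(8, 0.4, dim=6, seed=5)
        enc = GCNEncoder(in_dim=6, hidden_dim=7, out_dim=5, seed=1)
        H = enc.forward(ContrastiveView(net.A, net.X)).data
        H_oracle = gcn_forward_dense(net.A, net.X, enc.W1.data, enc.b1.data,
                                     enc.W2.data, enc.b2.data)
        assert np.abs(H - H_oracle).max() <= 1e-6

    def test_path_graph_against_oracle(self):
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=np.int8)
        X = np.random.default_rng(0).standard_normal((3, 4))
        enc = GCNEncoder(in_dim=4, hidden_dim=4, out_dim=4, seed=2)
        H = enc.forward(ContrastiveView(A, X)).data
        assert np.abs(H - gcn_forward_dense(A, X, enc.W1.data, enc.b1.data,
                                            enc.W2.data, enc.b2.data)).max() <= 1e-6

    def test_permutation_equivariance(self):
        net = _random_network(10, 0.5, dim=8, seed=6)
        enc = GCNEncoder(in_dim=8, seed=3)
        H = enc.forward(ContrastiveView(net.A, net.X)).data
        perm = np.random.default_rng(1).permutation(10)
        Hp = enc.forward(ContrastiveView(net.A[perm][:, perm], net.X[perm])).data
        assert np.allclose(Hp, H[perm], atol=1e-8)

    def test_isolated_node_self_only(self):
        A = np.zeros((1, 1), dtype=np.int8)
        X = np.ones((1, 4))
        enc = GCNEncoder(in_dim=4, seed=0)
        H = enc.forward(ContrastiveView(A, X)).data
        # normalization with self-loop leaves the single node's features intact
        expected = gcn_forward_dense(A, X, enc.W1.data, enc.b1.data,
                                     enc.W2.data, enc.b2.data)
        assert np.allclose(H, expected)

    def test_dim_mismatch_rejected(self):
        enc = GCNEncoder(in_dim=4, seed=0)
        with pytest.raises(ValueError):
            enc.forward(ContrastiveView(np.zeros((2, 2), dtype=np.int8),
                                        np.zeros((2, 5))))


class TestLossAndEMA:
    def test_analytic_limits(self):
        rng = np.random.default_rng(0)
        Z = rng.standard_normal((6, 4))
        assert contrastive_loss(ag.constant(Z), ag.constant(Z.copy())).data \
            == pytest.approx(-2.0)
        assert contrastive_loss(ag.constant(Z), ag.constant(-Z)).data \
            == pytest.approx(2.0)
        A = np.zeros((4, 2)); A[:, 0] = 1.0
        B = np.zeros((4, 2)); B[:, 1] = 1.0
        assert contrastive_loss(ag.constant(A), ag.constant(B)).data \
            == pytest.approx(0.0)

    def test_loss_bounded_and_zero_norm_rows(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            Z = rng.standard_normal((5, 3))
            H = rng.standard_normal((5, 3))
            Z[0] = 0.0
            val = float(contrastive_loss(ag.constant(Z), ag.constant(H)).data)
            assert -2.0 <= val <= 2.0
            assert np.isfinite(val)

    def test_gradient_only_through_online_branch(self):
        Z = ag.parameter(np.random.default_rng(2).standard_normal((4, 3)))
        H = ag.parameter(np.random.default_rng(3).standard_normal((4, 3)))
        loss = contrastive_loss(Z, H.detach())
        loss.backward()
        assert Z.grad is not None
        assert H.grad is None

    def test_ema_boundaries_and_arithmetic(self):
        a = GCNEncoder(in_dim=3, hidden_dim=3, out_dim=3, seed=0)
        b = GCNEncoder(in_dim=3, hidden_dim=3, out_dim=3, seed=1)
        before = [p.data.copy() for p in b.parameters()]
        ema_update(b, a, 1.0)
        for p, prev in zip(b.parameters(), before):
            assert np.array_equal(p.data, prev)
        ema_update(b, a, 0.0)
        for p, q in zip(b.parameters(), a.parameters()):
            assert np.array_equal(p.data, q.data)
        x = GCNEncoder(in_dim=1, hidden_dim=1, out_dim=1, seed=0)
        y = GCNEncoder(in_dim=1, hidden_dim=1, out_dim=1, seed=0)
        x.W1.data[:] = 1.0
        y.W1.data[:] = 0.0
        ema_update(x, y, 0.99)
        assert x.W1.data[0, 0] == pytest.approx(0.99)

    def test_ema_contracts_toward_fixed_online(self):
        target = GCNEncoder(in_dim=4, seed=0)
        online = GCNEncoder(in_dim=4, seed=1)
        def dist():
            return sum(float(np.linalg.norm(p.data - q.data))
                       for p, q in zip(target.parameters(), online.parameters()))
        prev = dist()
        for _ in range(5):
            ema_update(target, online, 0.9)
            cur = dist()
            assert cur < prev
            prev = cur


class TestTraining:
    def test_loss_decreases_on_two_block_graph(self):
        net, _ = _two_block_network(n=20, seed=7)
        state = train_gcl(net, epochs=200, p_edge=0.2, p_feat=0.2, seed=0)
        assert state.loss_history[-1] < state.loss_history[0]

    def test_zero_lr_freezes_online_encoder(self):
        net = _random_network(10, 0.4, seed=8)
        state = train_gcl(net, epochs=5, lr=0.0, seed=0)
        fresh = train_gcl(net, epochs=0, seed=0)
        for p, q in zip(state.online.parameters(), fresh.online.parameters()):
            assert np.array_equal(p.data, q.data)

    def test_deterministic_loss_history(self):
        net = _random_network(12, 0.4, seed=9)
        h1 = train_gcl(net, epochs=10, seed=5).loss_history
        h2 = train_gcl(net, epochs=10, seed=5).loss_history
        assert h1 == h2

    def test_extracted_features_shape_and_block_separation(self):
        net, blocks = _two_block_network(n=40, seed=10)
        state = train_gcl(net, epochs=300, seed=1)
        Z = extract_relational_features(state.online, net)
        assert Z.shape == (40, 300)
        assert np.isfinite(Z).all()
        Zn = Z / np.linalg.norm(Z, axis=1, keepdims=True)
        C = Zn @ Zn.T
        same = blocks[:, None] == blocks[None, :]
        off_diag = ~np.eye(40, dtype=bool)
        within = C[same & off_diag].mean()
        between = C[~same].mean()
        assert within - between > 0.1

    def test_untrained_encoder_still_valid_output(self):
        net = _random_network(6, 0.3, seed=11)
        enc = GCNEncoder(in_dim=net.X.shape[1], seed=0)
        Z = extract_relational_features(enc, net)
        assert Z.shape == (6, 300)


def test_predictor_is_affine():
    pred = Predictor(dim=4, seed=0)
    H = np.random.default_rng(0).standard_normal((3, 4))
    out = pred.forward(ag.constant(H)).data
    assert np.allclose(out, H @ pred.W.data + pred.b.data, atol=1e-12)


def test_normalized_adjacency_row_normalization():
    A = np.array([[0, 1], [1, 0]])
    n = normalized_adjacency(A)
    assert np.allclose(n, np.full((2, 2), 0.5))
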