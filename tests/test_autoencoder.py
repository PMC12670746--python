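import numpy as np
import pytest

from spiceist.autoencoder import (
    EarlyStopper,
    GraphAutoencoder,
    compute_loss,
    early_stopping_trace,
    pool_cell,
)
from spiceist.graphs import batch_graphs, build_cell_graph
from spiceist.gridding import CellGrid


def _random_graph(rng, n_grids=6, M=5, K=4, span=4):
    cells = set()
    while len(cells) < n_grids:
        cells.add((int(rng.integers(0, span)), int(rng.integers(0, span))))
    idx = np.array(sorted(cells))
    idx = idx[np.lexsort((idx[:, 0], idx[:, 1]))]
    cg = CellGrid("c", idx, np.abs(rng.normal(size=(n_grids, M))))
    feat = np.abs(rng.normal(size=(n_grids, M)))
    return build_cell_graph(feat, cg, rng.normal(size=K))


@pytest.fixture
def small_batch(rng):
    graphs = [_random_graph(rng, n_grids=4 + i) for i in range(3)]
    return graphs, batch_graphs(graphs, latent_dim=8)


class TestComputeLoss:
    def test_perfect_reconstruction_and_pooling_is_zero(self):
        x = np.ones((3, 2))
        pooled = np.ones((1, 4))
        loss = compute_loss(x, x, pooled, pooled, alpha=0.5, cell_index=np.zeros(3, dtype=int))
        assert loss.total == 0.0

    def test_alpha_zero_reduces_to_reconstruction(self, rng):
        recon = rng.normal(size=(4, 3))
        x = rng.normal(size=(4, 3))
        pooled = rng.normal(size=(2, 5))
        z = rng.normal(size=(2, 5))
        loss = compute_loss(recon, x, pooled, z, 0.0, np.array([0, 0, 1, 1]))
        assert loss.total == loss.reconstruction

    def test_hand_worked_example(self):
        # 1 cell, 2 nodes, M=2; recon - input = [[1,0],[0,1]]; pooled - z = [2,0,...]
        x = np.zeros((2, 2))
        recon = np.eye(2)
        z = np.zeros((1, 64))
        pooled = z.copy()
        pooled[0, 0] = 2.0
        loss = compute_loss(recon, x, pooled, z, alpha=0.3, cell_index=np.zeros(2, dtype=int))
        # L_recon: (1+1) / (2 nodes * 2 genes) = 0.5
        assert loss.reconstruction == pytest.approx(0.5)
        # L_embed: per-element MSE over the 64 latent dims = 4/64
        assert loss.embedding == pytest.approx(4.0 / 64.0)
        assert loss.total == pytest.approx(0.5 + 0.3 * 4.0 / 64.0)

    def test_additivity_exact(self, rng):
        recon = rng.normal(size=(5, 3))
        x = rng.normal(size=(5, 3))
        pooled = rng.normal(size=(2, 6))
        z = rng.normal(size=(2, 6))
        loss = compute_loss(recon, x, pooled, z, 1.7, np.array([0, 0, 0, 1, 1]))
        assert loss.total == loss.reconstruction + 1.7 * loss.embedding

    def test_scalar_loop_oracle(self, rng):
        cell_index = np.array([0, 0, 1, 1, 1])
        recon = rng.normal(size=(5, 3))
        x = rng.normal(size=(5, 3))
        pooled = rng.normal(size=(2, 4))
        z = rng.normal(size=(2, 4))
        loss = compute_loss(recon, x, pooled, z, 0.9, cell_index)
        l1 = 0.0
        for c, nodes in ((0, [0, 1]), (1, [2, 3, 4])):
            s = sum((recon[g, m] - x[g, m]) ** 2 for g in nodes for m in range(3))
            l1 += s / (len(nodes) * 3)
        l1 /= 2
        l2 = sum((pooled[c, d] - z[c, d]) ** 2 for c in range(2) for d in range(4)) / (2 * 4)
        assert loss.reconstruction == pytest.approx(l1, rel=1e-12)
        assert loss.embedding == pytest.approx(l2, rel=1e-12)

    def test_nonfinite_rejected(self):
        x = np.ones((2, 2))
        bad = x.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            compute_loss(bad, x, np.ones((1, 2)), np.ones((1, 2)), 0.1, np.zeros(2, dtype=int))

    def test_loss_gradient_matches_numerical(self, rng):
        # gradient of the loss w.r.t. recon and pooled on a 2-node toy
        x = rng.normal(size=(2, 2))
        z = rng.normal(size=(1, 3))
        cell_index = np.zeros(2, dtype=int)
        recon = rng.normal(size=(2, 2))
        pooled = rng.normal(size=(1, 3))
        alpha = 0.6

        def total(r, p):
            return compute_loss(r, x, p, z, alpha, cell_index).total

        g_recon = 2.0 * (recon - x) / (1 * 2 * 2)
        g_pooled = 2.0 * alpha * (pooled - z) / (1 * 3)
        eps = 1e-6
        for arr, grad in ((recon, g_recon), (pooled, g_pooled)):
            for i in np.ndindex(arr.shape):
                orig = arr[i]
                arr[i] = orig + eps
                up = total(recon, pooled)
                arr[i] = orig - eps
                dn = total(recon, pooled)
                arr[i] = orig
                num = (up - dn) / (2 * eps)
                assert num == pytest.approx(grad[i], rel=1e-4, abs=1e-9)


class TestNetworkGradients:
    def test_analytic_matches_numerical_gradients(self, small_batch):
        _, batch = small_batch
        model = GraphAutoencoder(
            alpha=0.7, hidden_dim=6, latent_dim=8, decoder_hidden_dim=5, dropout=0.0
        )
        params = model._init_params(5, np.random.default_rng(1))
        _, grads = model.loss_and_grads(params, model._init_bn_stats(), batch, training=True)
        eps = 1e-6
        check_rng = np.random.default_rng(9)
        for key, arr in params.items():
            flat = arr.ravel()
            for i in check_rng.integers(0, flat.size, size=min(4, flat.size)):
                orig = flat[i]
                flat[i] = orig + eps
                up = model.loss_and_grads(
                    params, model._init_bn_stats(), batch, training=True
                )[0].total
                flat[i] = orig - eps
                dn = model.loss_and_grads(
                    params, model._init_bn_stats(), batch, training=True
                )[0].total
                flat[i] = orig
                num = (up - dn) / (2 * eps)
                ana = grads[key].ravel()[i]
                assert num == pytest.approx(ana, rel=1e-4, abs=1e-7), key


class TestEncodeDecode:
    def _fitted(self, graphs):
        model = GraphAutoencoder(
            hidden_dim=8, latent_dim=6, decoder_hidden_dim=7, epochs=2,
            batches_per_epoch=2, batch_size=2, random_state=0,
        )
        return model.fit(graphs)

    def test_eval_mode_deterministic(self, small_batch):
        graphs, batch = small_batch
        model = self._fitted(graphs)
        h1 = model.encode(batch)
        h2 = model.encode(batch)
        np.testing.assert_array_equal(h1, h2)

    def test_single_node_graph_uses_self_loop(self, rng):
        g = _random_graph(rng, n_grids=1)
        model = self._fitted([g, _random_graph(rng, n_grids=3)])
        batch = batch_graphs([g], latent_dim=6)
        h = model.encode(batch)
        assert h.shape == (1, 6)
        assert np.all(np.isfinite(h))

    def test_permutation_equivariance(self, rng):
        """Relabelling nodes permutes encoder outputs identically.

        Batch norm uses the same batch statistics either way, so the output
        must permute exactly with the nodes.
        """
        g = _random_graph(rng, n_grids=6)
        batch = batch_graphs([g], latent_dim=8)
        model = GraphAutoencoder(hidden_dim=7, latent_dim=8, dropout=0.0)
        params = model._init_params(5, np.random.default_rng(2))
        bn = model._init_bn_stats()
        _, H, _, _ = model._forward(params, bn, batch, training=True)

        perm = np.random.default_rng(3).permutation(6)
        batch_p = batch_graphs([g], latent_dim=8)
        batch_p.X = batch.X[perm]
        batch_p.adj = batch.adj[perm][:, perm]
        _, H_p, _, _ = model._forward(params, model._init_bn_stats(), batch_p, training=True)
        np.testing.assert_allclose(H_p, H[perm], rtol=1e-9, atol=1e-12)

    def test_decode_shape_and_row_wise_consistency(self, small_batch, rng):
        graphs, _ = small_batch
        model = self._fitted(graphs)
        H = rng.normal(size=(5, 6))
        out = model.decode(H)
        assert out.shape == (5, 5)
        # decoding a stacked pair equals stacking decodings (node-wise map)
        top = model.decode(H[:2])
        np.testing.assert_allclose(out[:2], top, rtol=1e-12)

    def test_dimension_mismatch_rejected(self, small_batch, rng):
        graphs, _ = small_batch
        model = self._fitted(graphs)
        bad = _random_graph(rng, n_grids=3, M=9)
        with pytest.raises(ValueError, match="genes"):
            model.encode(batch_graphs([bad], latent_dim=6))


class TestPooling:
    def test_single_node_cell_returns_node_embedding(self, rng):
        h = rng.normal(size=(1, 4))
        np.testing.assert_array_equal(pool_cell(h, np.array([0])), h)

    def test_opposite_nodes_average_to_zero(self):
        v = np.array([[1.0, -2.0], [-1.0, 2.0]])
        np.testing.assert_allclose(pool_cell(v, np.array([0, 0])), [[0.0, 0.0]])

    def test_matches_direct_summation_oracle(self, rng):
        h = rng.normal(size=(7, 3))
        idx = np.array([0, 0, 1, 1, 1, 2, 2])
        pooled = pool_cell(h, idx)
        for c in range(3):
            np.testing.assert_allclose(pooled[c], h[idx == c].sum(axis=0) / (idx == c).sum())


class TestEarlyStopping:
    def test_hand_traced_sequence(self):
        # improvements of less than 1e-4 over the best never reset patience
        seq = [1.0, 0.9, 0.89995, 0.89999, 0.89998, 0.5, 0.4]
        n_run, best = early_stopping_trace(seq, min_delta=1e-4, patience=3)
        assert n_run == 5  # stops after 3 consecutive non-improving epochs
        assert best == 2  # last checkpoint that improved by > 1e-4

    def test_monotone_decrease_never_stops(self):
        seq = [1.0 - 0.01 * i for i in range(10)]
        n_run, best = early_stopping_trace(seq)
        assert n_run == 10 and best == 10

    def test_best_checkpoint_requires_significant_improvement(self):
        stopper = EarlyStopper(min_delta=1e-4, patience=2)
        assert stopper.update(1.0, 1) == (True, False)
        assert stopper.update(0.99995, 2) == (False, False)
        assert stopper.update(0.99994, 3) == (False, True)
        assert stopper.best_epoch == 1


class TestTraining:
    def _graphs(self, rng, n=24):
        return [_random_graph(rng, n_grids=3 + i % 5) for i in range(n)]

    def test_loss_decreases_on_synthetic_cells(self, rng):
        graphs = self._graphs(rng)
        model = GraphAutoencoder(
            hidden_dim=12, latent_dim=8, decoder_hidden_dim=10, epochs=8,
            batches_per_epoch=4, batch_size=8, random_state=0,
        )
        model.fit(graphs)
        assert model.history_[-1]["train_total"] < model.history_[0]["train_total"]

    def test_fixed_seed_reproduces_history(self, rng):
        graphs = self._graphs(rng)
        kwargs = dict(hidden_dim=8, latent_dim=8, epochs=3, batches_per_epoch=3,
                      batch_size=6, random_state=11)
        h1 = GraphAutoencoder(**kwargs).fit(graphs).history_
        h2 = GraphAutoencoder(**kwargs).fit(graphs).history_
        assert h1 == h2

    def test_best_checkpoint_selected(self, rng):
        graphs = self._graphs(rng)
        model = GraphAutoencoder(hidden_dim=8, latent_dim=8, epochs=6, batches_per_epoch=3,
                                 batch_size=6, random_state=1)
        model.fit(graphs)
        vals = [h["val_total"] for h in model.history_]
        # best epoch improved on every earlier epoch by more than min_delta
        best = model.best_epoch_
        assert vals[best - 1] <= min(vals[: best - 1], default=np.inf)

    def test_empty_and_singleton_inputs_rejected(self):
        with pytest.raises(ValueError):
            GraphAutoencoder().fit([])
        with pytest.raises(ValueError):
            GraphAutoencoder().fit([_random_graph(np.random.default_rng(0))])

    def test_save_load_round_trip(self, tmp_path, rng):
        graphs = self._graphs(rng, n=10)
        model = GraphAutoencoder(hidden_dim=8, latent_dim=8, epochs=2, batches_per_epoch=2,
                                 batch_size=4, random_state=4)
        model.fit(graphs)
        model.save(tmp_path / "model.npz")
        loaded = GraphAutoencoder.load(tmp_path / "model.npz")
        np.testing.assert_array_equal(model.transform(graphs), loaded.transform(graphs))

    def test_large_alpha_drives_pooled_latent_to_cell_target(self, rng):
        """Limiting behaviour of the dual objective: with a dominant
        cell-level weight the pooled latent aligns with the PCA target on
        the constrained dimensions."""
        graphs = self._graphs(rng, n=30)
        K = 4  # target rank below the latent width
        W = rng.normal(size=(5, K))  # targets are a learnable function of the features
        for g in graphs:
            g.cell_target = g.node_features.mean(axis=0) @ W
        model = GraphAutoencoder(
            alpha=1e3, hidden_dim=16, latent_dim=8, decoder_hidden_dim=8,
            epochs=400, batches_per_epoch=8, batch_size=15,
            early_stop_patience=400, random_state=0,
        )
        model.fit(graphs)
        pooled = model.transform(graphs)[:, :K]
        targets = np.vstack([g.cell_target for g in graphs])
        cos = np.sum(pooled * targets, axis=1) / (
            np.linalg.norm(pooled, axis=1) * np.linalg.norm(targets, axis=1)
        )
        assert cos.mean() > 0.9

    def test_sklearn_param_round_trip(self):
        model = GraphAutoencoder(alpha=0.5)
        params = model.get_params()
        assert params["alpha"] == 0.5
        model.set_params(alpha=2.0, epochs=7)
        assert model.alpha == 2.0 and model.epochs == 7
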