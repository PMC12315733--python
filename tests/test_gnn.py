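"""GCN/MLP model: analytic layer checks, gradient correctness, training."""

import numpy as np
import pytest

from sfcoupling import gnn, synth
from sfcoupling.errors import ConfigError, InvalidInputError
from sfcoupling.gnn import _forward_backward, _params_to_list


def tiny_model(k=3, c=2, mh=2, seed=0):
    cfg = gnn.GnnConfig(gcn_dims=(k, c, c), mlp_hidden=mh, seed=seed)
    return gnn.init_model(cfg, np.random.default_rng(seed))


class TestGcnLayer:
    def test_two_node_hand_computation(self):
        # A=[[0,1],[1,0]]: A+I has row sums 2, so the normalized operator
        # is [[.5,.5],[.5,.5]]; all pre-activations positive
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = gnn.gcn_layer(np.eye(2), a, np.eye(2), alpha=0.7)
        np.testing.assert_allclose(out, np.full((2, 2), 0.5), atol=1e-12)

    def test_zero_weights_give_zero_output(self, rng):
        a = np.abs(rng.normal(size=(4, 4))); a = a + a.T
        np.fill_diagonal(a, 0)
        out = gnn.gcn_layer(np.eye(4), a, np.zeros((4, 3)), alpha=0.25)
        assert np.all(out == 0)

    def test_alpha_one_is_linear(self, rng):
        a = np.abs(rng.normal(size=(5, 5))); a = a + a.T
        np.fill_diagonal(a, 0)
        h = rng.normal(size=(5, 4))
        w = rng.normal(size=(4, 3))
        s = gnn.normalized_adjacency(a)
        np.testing.assert_allclose(gnn.gcn_layer(h, a, w, alpha=1.0),
                                   s @ h @ w, atol=1e-12)

    def test_nonfinite_input_rejected(self):
        a = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(InvalidInputError):
            gnn.normalized_adjacency(a)


class TestEncode:
    def path_graph(self, k=6):
        a = np.zeros((k, k))
        for i in range(k - 1):
            a[i, i + 1] = a[i + 1, i] = 1.0
        return a

    def test_two_layer_locality_on_path(self):
        # with L=2, node 0's embedding depends only on its 2-hop
        # neighborhood; removing the far edge (4,5) leaves it unchanged
        model = tiny_model(k=6, c=4)
        a = self.path_graph(6)
        full = gnn.encode(a, model)[-1]
        cut = a.copy(); cut[4, 5] = cut[5, 4] = 0.0
        partial = gnn.encode(cut, model)[-1]
        np.testing.assert_allclose(full[0], partial[0], atol=1e-12)
        np.testing.assert_allclose(full[1], partial[1], atol=1e-12)
        assert not np.allclose(full[5], partial[5])

    def test_one_hot_relabeling_permutes_embeddings(self, rng):
        # permuting node labels and permuting the one-hot inputs the
        # same way permutes the embedding rows identically
        k = 5
        a = np.abs(rng.normal(size=(k, k))); a = a + a.T
        np.fill_diagonal(a, 0)
        w = rng.normal(size=(k, 3))
        perm = rng.permutation(k)
        p = np.eye(k)[perm]
        base = gnn.gcn_layer(np.eye(k), a, w, 0.25)
        relabeled = gnn.gcn_layer(p, p @ a @ p.T, w, 0.25)
        np.testing.assert_allclose(relabeled, p @ base, atol=1e-12)

    def test_encode_deterministic_and_starts_from_identity(self):
        model = tiny_model(k=6, c=4)
        a = self.path_graph(6)
        hs1 = gnn.encode(a, model)
        hs2 = gnn.encode(a, model)
        assert np.array_equal(hs1[0], np.eye(6))
        for x, y in zip(hs1, hs2):
            assert np.array_equal(x, y)

    def test_shape_mismatch_rejected(self):
        model = tiny_model(k=4, c=2)
        with pytest.raises(ConfigError):
            gnn.encode(np.zeros((5, 5)), model)


class TestDecode:
    def test_zero_mlp_outputs_zero(self):
        model = tiny_model(k=3, c=2, mh=2)
        model.w1[:] = 0; model.b1[:] = 0; model.w2[:] = 0; model.b2 = 0.0
        assert gnn.decode_edge(np.array([1.0, 2.0]), np.array([3.0, 4.0]),
                               model) == 0.0

    def test_hand_arithmetic_relu_path(self):
        model = tiny_model(k=3, c=1, mh=1)
        model.w1 = np.array([[1.0], [1.0]])
        model.b1 = np.zeros(1)
        model.w2 = np.array([1.0])
        model.b2 = 0.0
        assert gnn.decode_edge(np.array([0.3]), np.array([0.4]),
                               model) == pytest.approx(0.7)
        assert gnn.decode_edge(np.array([-0.3]), np.array([-0.4]),
                               model) == 0.0


class TestPredictFc:
    def test_symmetric_zero_diagonal(self, rng):
        model = tiny_model(k=5, c=3, mh=4, seed=2)
        a = np.abs(rng.normal(size=(5, 5))); a = a + a.T
        np.fill_diagonal(a, 0)
        p = gnn.predict_fc(a, model)
        assert np.array_equal(p, p.T)
        assert np.all(np.diag(p) == 0)

    def test_matches_double_loop_decode_oracle(self, rng):
        model = tiny_model(k=3, c=2, mh=3, seed=5)
        a = np.array([[0.0, 1.0, 0.5], [1.0, 0.0, 2.0], [0.5, 2.0, 0.0]])
        p = gnn.predict_fc(a, model)
        h = gnn.encode(a, model)[-1]
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                expect = 0.5 * (gnn.decode_edge(h[i], h[j], model)
                                + gnn.decode_edge(h[j], h[i], model))
                assert p[i, j] == pytest.approx(expect, abs=1e-12)


class TestLoss:
    def test_perfect_prediction_zero_loss(self):
        model = tiny_model()
        m = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert gnn.mse_l2_loss([m], [m], model, 0.0) == 0.0

    def test_unit_error_two_node_formula(self):
        model = tiny_model()
        p = np.array([[0.0, 1.0], [1.0, 0.0]])
        e = np.zeros((2, 2))
        # (1/(K(K-1))) * sum over ordered pairs = (1/2) * 2 = 1
        assert gnn.mse_l2_loss([p], [e], model, 0.0) == pytest.approx(1.0)

    def test_l2_penalty_additivity(self):
        model = tiny_model(seed=3)
        m = np.zeros((3, 3))
        base = gnn.mse_l2_loss([m], [m], model, 0.0)
        withl2 = gnn.mse_l2_loss([m], [m], model, 0.1)
        assert withl2 - base == pytest.approx(0.1 * model.mlp_weight_sq_norm())

    def test_matches_naive_double_loop_oracle(self, rng):
        model = tiny_model(seed=4)
        k, nb = 5, 3
        ps = [rng.normal(size=(k, k)) for _ in range(nb)]
        es = [rng.normal(size=(k, k)) for _ in range(nb)]
        lam = 0.01
        expect = 0.0
        for p, e in zip(ps, es):
            acc = 0.0
            for i in range(k):
                for j in range(k):
                    if i != j:
                        acc += (p[i, j] - e[i, j]) ** 2
            expect += acc / (k * (k - 1))
        expect = expect / nb + lam * (np.sum(model.w1**2) + np.sum(model.w2**2))
        assert gnn.mse_l2_loss(ps, es, model, lam) == pytest.approx(
            expect, abs=1e-12)

    def test_negative_lambda_rejected(self):
        model = tiny_model()
        with pytest.raises(ConfigError):
            gnn.mse_l2_loss([np.zeros((2, 2))], [np.zeros((2, 2))], model, -1.0)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        # K=6 toy; central differences on a random subset of parameters
        rng = np.random.default_rng(0)
        k = 6
        a = np.abs(rng.normal(size=(k, k))); a = a + a.T
        np.fill_diagonal(a, 0)
        s = gnn.normalized_adjacency(a)
        efc = rng.normal(size=(k, k)); efc = 0.5 * (efc + efc.T)
        np.fill_diagonal(efc, 0)
        model = tiny_model(k=k, c=4, mh=5, seed=1)

        _, grads = _forward_backward(s, efc, model)
        glist = (grads["gcn"] + [grads["alpha"], grads["w1"], grads["b1"],
                                 grads["w2"], np.array([grads["b2"]])])
        params = _params_to_list(model)
        h = 1e-6
        checked = 0
        for pi in range(len(params)):
            flat = params[pi].reshape(-1)
            for idx in rng.choice(flat.size, size=min(3, flat.size),
                                  replace=False):
                is_b2 = pi == len(params) - 1
                orig = flat[idx]
                if is_b2:
                    model.b2 = orig + h
                else:
                    flat[idx] = orig + h
                lp, _ = _forward_backward(s, efc, model)
                if is_b2:
                    model.b2 = orig - h
                else:
                    flat[idx] = orig - h
                lm, _ = _forward_backward(s, efc, model)
                if is_b2:
                    model.b2 = orig
                else:
                    flat[idx] = orig
                fd = (lp - lm) / (2 * h)
                an = glist[pi].reshape(-1)[idx]
                assert an == pytest.approx(fd, rel=1e-4, abs=1e-8)
                checked += 1
        assert checked >= 5


class TestSplit:
    def test_even_split_and_partition(self):
        tr, te = gnn.split_cohort(list(range(10)), seed=0)
        assert len(tr) == 5 and len(te) == 5
        assert sorted(tr + te) == list(range(10))
        assert not set(tr) & set(te)

    def test_reproducible(self):
        assert gnn.split_cohort(list(range(9)), seed=3) == \
            gnn.split_cohort(list(range(9)), seed=3)

    def test_too_small_rejected(self):
        with pytest.raises(InvalidInputError):
            gnn.split_cohort([1, 2, 3])


@pytest.fixture(scope="module")
def trainable_cohort():
    spec = synth.CohortSpec(n_subjects=8, n_regions=20, seed=21)
    cohort = synth.generate_cohort(spec)
    return [s.sc for s in cohort.subjects], [s.fc for s in cohort.subjects]


class TestTraining:
    def test_loss_decreases(self, trainable_cohort):
        scs, fcs = trainable_cohort
        cfg = gnn.GnnConfig(gcn_dims=(20, 16, 16), mlp_hidden=16, epochs=30,
                            seed=0)
        _, losses = gnn.train_model(scs, fcs, cfg)
        assert losses[-1] < losses[0]

    def test_training_deterministic(self, trainable_cohort):
        scs, fcs = trainable_cohort
        cfg = gnn.GnnConfig(gcn_dims=(20, 8, 8), mlp_hidden=8, epochs=5,
                            seed=9)
        _, l1 = gnn.train_model(scs, fcs, cfg)
        _, l2 = gnn.train_model(scs, fcs, cfg)
        np.testing.assert_array_equal(l1, l2)

    def test_fits_its_own_forward_family(self):
        # FC = standardized 1-hop latent exactly: the model must reach a
        # training loss well below the target variance (which is 1)
        spec = synth.CohortSpec(n_subjects=8, n_regions=20, betas=(1.0,),
                                group_scale=0.0, indiv_scale=0.0,
                                noise_sd=0.0, sc_obs_sd=0.0, flip_rate=0.0,
                                seed=33)
        cohort = synth.generate_cohort(spec)
        scs = [s.sc for s in cohort.subjects]
        fcs = [s.fc for s in cohort.subjects]
        iu = np.triu_indices(20, 1)
        var = np.var(np.concatenate([f[iu] for f in fcs]))
        cfg = gnn.GnnConfig(gcn_dims=(20, 32, 32), mlp_hidden=64, epochs=400,
                            learning_rate=0.01, seed=0)
        _, losses = gnn.train_model(scs, fcs, cfg)
        assert losses[-1] < 0.1 * var

    def test_config_k_mismatch_rejected(self, trainable_cohort):
        scs, fcs = trainable_cohort
        cfg = gnn.GnnConfig(gcn_dims=(19, 8, 8), mlp_hidden=4, epochs=1)
        with pytest.raises(ConfigError):
            gnn.train_model(scs, fcs, cfg)


class TestCheckpoint:
    def test_save_load_round_trip_preserves_predictions(self, rng, tmp_path):
        model = tiny_model(k=5, c=3, mh=4, seed=11)
        a = np.abs(rng.normal(size=(5, 5))); a = a + a.T
        np.fill_diagonal(a, 0)
        gnn.save_model(model, tmp_path / "model.json")
        restored = gnn.load_model(tmp_path / "model.json")
        np.testing.assert_array_equal(gnn.predict_fc(a, restored),
                                      gnn.predict_fc(a, model))
        assert restored.config == model.config


class TestGroupLevelPredict:
    def test_single_subject_reduces_to_predict_fc(self, rng):
        model = tiny_model(k=4, c=3, mh=4, seed=8)
        a = np.abs(rng.normal(size=(4, 4))); a = a + a.T
        np.fill_diagonal(a, 0)
        fc = rng.normal(size=(4, 4)); fc = 0.5 * (fc + fc.T)
        pred, emp = gnn.group_level_predict(model, [a], [fc])
        np.testing.assert_array_equal(pred, gnn.predict_fc(a, model))
        np.testing.assert_array_equal(emp, fc)

    def test_mean_sc_is_hand_average(self, rng):
        model = tiny_model(k=4, c=3, mh=4, seed=8)
        mats = [np.abs(rng.normal(size=(4, 4))) for _ in range(2)]
        mats = [0.5 * (m + m.T) for m in mats]
        for m in mats:
            np.fill_diagonal(m, 0)
        pred, _ = gnn.group_level_predict(model, mats, mats)
        np.testing.assert_array_equal(
            pred, gnn.predict_fc((mats[0] + mats[1]) / 2, model))

    def test_empty_test_set_rejected(self):
        model = tiny_model()
        with pytest.raises(InvalidInputError):
            gnn.group_level_predict(model, [], [])
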