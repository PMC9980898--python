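"""The connectome CNN: layer formulas against nested-loop oracles,
architecture contracts, and training behaviour."""

import numpy as np
import pytest
from scipy import stats

from connectomepred import dlmodel as dl
from connectomepred import preprocess, synth
from connectomepred.linear import fit_ridge


def e2e_loop(A, wr, wc):
    """Independent nested-loop implementation of the edge-to-edge filter."""
    B, F, n, _ = A.shape
    M = wr.shape[1]
    out = np.zeros((B, M, n, n))
    for b in range(B):
        for m in range(M):
            for i in range(n):
                for j in range(n):
                    s = 0.0
                    for f in range(F):
                        s += A[b, f, i, :] @ wr[f, m] + A[b, f, :, j] @ wc[f, m]
                    out[b, m, i, j] = s
    return out


def e2n_loop(A, wr):
    B, F, n, _ = A.shape
    M = wr.shape[1]
    out = np.zeros((B, M, n))
    for b in range(B):
        for m in range(M):
            for i in range(n):
                out[b, m, i] = sum(A[b, f, i, :] @ wr[f, m] for f in range(F))
    return out


class TestLayerFormulas:
    def test_e2e_worked_example(self):
        A = np.array([[[[0.0, 1.0], [1.0, 0.0]]]])
        wr = np.ones((1, 1, 2))
        wc = np.ones((1, 1, 2))
        out = dl.e2e_forward(A, wr, wc)
        assert np.allclose(out, 2.0)  # rowsum + colsum = 1 + 1 everywhere

    def test_zero_weights_give_zero_output(self, rng):
        A = rng.normal(size=(2, 3, 5, 5))
        out = dl.e2e_forward(A, np.zeros((3, 2, 5)), np.zeros((3, 2, 5)))
        assert np.all(out == 0)

    def test_e2e_matches_loop_oracle(self, rng):
        A = rng.normal(size=(3, 2, 6, 6))
        wr = rng.normal(size=(2, 4, 6))
        wc = rng.normal(size=(2, 4, 6))
        assert np.abs(dl.e2e_forward(A, wr, wc) - e2e_loop(A, wr, wc)).max() < 1e-6

    def test_e2n_unit_weights_give_node_strengths(self, rng):
        A = preprocess.symmetrize(rng.random((2, 5, 5)))[:, None]
        out = dl.e2n_forward(A, np.ones((1, 1, 5)))
        assert np.allclose(out[:, 0], A[:, 0].sum(axis=2))
        assert np.all(dl.e2n_forward(np.zeros((1, 1, 5, 5)),
                                     np.ones((1, 1, 5))) == 0)

    def test_e2n_matches_loop_oracle(self, rng):
        A = rng.normal(size=(2, 3, 6, 6))
        wr = rng.normal(size=(3, 5, 6))
        assert np.abs(dl.e2n_forward(A, wr) - e2n_loop(A, wr)).max() < 1e-6

    def test_e2e_linearity(self, rng):
        A = rng.normal(size=(1, 1, 6, 6))
        B = rng.normal(size=(1, 1, 6, 6))
        wr = rng.normal(size=(1, 2, 6))
        wc = rng.normal(size=(1, 2, 6))
        f = lambda X: dl.e2e_forward(X, wr, wc)
        assert np.allclose(f(2.5 * A), 2.5 * f(A))
        assert np.allclose(f(A + B), f(A) + f(B))

    def test_symmetric_input_can_give_asymmetric_output(self, rng):
        """Independently trained row and column weights break symmetry —
        the reason gradient maps are symmetrized downstream."""
        A = preprocess.symmetrize(rng.random((1, 6, 6)))[:, None]
        wr = rng.normal(size=(1, 1, 6))
        wc = rng.normal(size=(1, 1, 6))
        out = dl.e2e_forward(A, wr, wc)[0, 0]
        assert not np.allclose(out, out.T)

    def test_shape_mismatch_rejected(self, rng):
        A = rng.normal(size=(1, 1, 6, 6))
        with pytest.raises(ValueError):
            dl.e2e_forward(A, np.ones((1, 1, 5)), np.ones((1, 1, 5)))
        with pytest.raises(ValueError):
            dl.e2n_forward(A, np.ones((2, 1, 6)))


class TestArchitecture:
    def test_covariate_head_parameter_arithmetic(self):
        base = dl.build_network(dl.ArchitectureSpec(n_nodes=10), seed=0)
        with_cov = dl.build_network(
            dl.ArchitectureSpec(n_nodes=10, with_covariates=True,
                                n_covariates=2), seed=0)
        extra = with_cov.parameter_count() - base.parameter_count()
        assert extra == 2 * base.spec.n_outputs  # 2 covariates x head outputs

    def test_large_input_flows_through(self, rng):
        spec = dl.ArchitectureSpec(n_nodes=85, e2e_filters=2, e2n_filters=2,
                                   n2g_units=4)
        net = dl.build_network(spec, seed=0)
        out = net.forward(preprocess.symmetrize(rng.random((2, 85, 85))))
        assert out.shape == (2, 2)

    def test_init_is_seed_deterministic(self):
        spec = dl.ArchitectureSpec(n_nodes=8)
        a = dl.build_network(spec, seed=42)
        b = dl.build_network(spec, seed=42)
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            dl.ArchitectureSpec(n_nodes=8, with_covariates=True, n_covariates=0)
        with pytest.raises(ValueError):
            dl.ArchitectureSpec(n_nodes=8, dropout_rate=1.0)
        with pytest.raises(ValueError):
            dl.ArchitectureSpec(n_nodes=8, task="ranking")


def separable_sex_cohort(n=200, seed=2):
    """Toy cohort with a huge planted sex effect; linear separability is
    verified by a logistic-ridge oracle before the CNN is asked to learn it."""
    truth = synth.make_truth(16, seed=0, n_sex_edges=20, sex_size=3.0,
                             n_age_edges=0, age_size=0.0, g_sd=0.0, p_sd=0.0,
                             scale_confound_beta=0.0)
    c = synth.generate_cohort(n, 16, truth=truth, seed=seed)
    X = preprocess.max_normalize(preprocess.symmetrize(c.matrices["SC"]))
    y = c.phenotypes["sex"].to_numpy(float)
    return X, y


class TestTraining:
    def test_learns_separable_sex_task(self):
        X, y = separable_sex_cohort()
        # linear oracle: the task is separable for a logistic model
        Xv = preprocess.vectorize_upper(X)
        lin = fit_ridge(Xv[:140], y[:140], lam=1e-3, task="classification")
        oracle_acc = np.mean((lin.decision(Xv[140:]) > 0) == (y[140:] > 0.5))
        assert oracle_acc >= 0.95
        net = dl.build_network(
            dl.ArchitectureSpec(n_nodes=16, task="classification"), seed=0)
        cfg = dl.TrainingConfig(epochs=60, seed=0)
        dl.train_network(net, (X[:140], y[:140]), (X[140:], y[140:]), cfg)
        assert max(net.history["val_metric"]) >= 0.95
        assert len(net.history["val_metric"]) == 60
        assert 1 <= net.best_epoch <= 60
        # AUC on held-out data
        pred = net.predict(X[140:])
        order = stats.rankdata(pred)
        pos = y[140:] > 0.5
        auc = (order[pos].sum() - pos.sum() * (pos.sum() + 1) / 2) / (
            pos.sum() * (~pos).sum())
        assert auc > 0.95

    def test_shuffled_labels_give_chance_accuracy(self):
        X, y = separable_sex_cohort(seed=3)
        rng = np.random.default_rng(0)
        y_shuf = rng.permutation(y)
        net = dl.build_network(
            dl.ArchitectureSpec(n_nodes=16, task="classification"), seed=1)
        cfg = dl.TrainingConfig(epochs=30, seed=1)
        dl.train_network(net, (X[:140], y_shuf[:140]),
                         (X[140:160], y_shuf[140:160]), cfg)
        acc = np.mean((net.predict(X[160:]) > 0.5) == (y_shuf[160:] > 0.5))
        assert 0.25 <= acc <= 0.75

    def test_training_is_seed_deterministic(self):
        X, y = separable_sex_cohort(n=60, seed=5)
        outs = []
        for _ in range(2):
            net = dl.build_network(
                dl.ArchitectureSpec(n_nodes=16, task="classification"), seed=3)
            cfg = dl.TrainingConfig(epochs=5, seed=3)
            dl.train_network(net, (X[:40], y[:40]), (X[40:], y[40:]), cfg)
            outs.append(net.predict(X[40:]))
        assert np.array_equal(outs[0], outs[1])

    def test_prediction_contracts(self):
        X, y = separable_sex_cohort(n=40, seed=6)
        net = dl.build_network(
            dl.ArchitectureSpec(n_nodes=16, task="classification"), seed=0)
        probs = net.predict_proba(X)
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert np.array_equal(net.predict(X), net.predict(X))  # dropout off
        with pytest.raises(ValueError):
            cfg = dl.TrainingConfig(loss="mean-squared-error")
            dl.train_network(net, (X[:20], y[:20]), (X[20:], y[20:]), cfg)

    def test_covariates_required_when_enabled(self, rng):
        spec = dl.ArchitectureSpec(n_nodes=6, with_covariates=True,
                                   n_covariates=2)
        net = dl.build_network(spec, seed=0)
        with pytest.raises(ValueError):
            net.forward(preprocess.symmetrize(rng.random((2, 6, 6))))
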