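"""SPD network layers, backprop correctness, manifold constraint, training."""

import numpy as np
import pytest

from neurospd import SPDNet, TrainConfig, matrix_log
from neurospd.exceptions import ConfigError, DataError
from neurospd.spdnet import (
    bimap_forward,
    default_bimap_dims,
    logeig_forward,
    reeig_forward,
)

from conftest import random_spd


def spd_batch(rng, n, d):
    A = rng.standard_normal((n, d, d))
    return A @ A.swapaxes(1, 2) + 0.5 * d * np.eye(d)


class TestLayers:
    def test_bimap_orthonormal_rows_map_identity_to_identity(self, rng):
        net = SPDNet(8, bimap_dims=(5,), seed=0)
        out = bimap_forward(np.eye(8), net.W[0])
        np.testing.assert_allclose(out, np.eye(5), atol=1e-12)

    def test_reference_dimension_chain(self):
        net = SPDNet(62)
        assert net.dims == (62, 31, 20, 16, 12)
        S = random_spd(np.random.default_rng(0), 62)
        first = bimap_forward(S, net.W[0])
        assert first.shape == (31, 31)
        assert net.feature_dim == 144

    def test_bimap_preserves_positive_definiteness(self, rng):
        for _ in range(20):
            S = random_spd(rng, 7)
            W = rng.standard_normal((4, 7))  # full row rank a.s.
            out = bimap_forward(S, W)
            assert np.linalg.eigvalsh(out).min() > 0

    def test_bimap_dimension_mismatch(self, rng):
        with pytest.raises(ConfigError):
            bimap_forward(np.eye(5), rng.standard_normal((3, 4)))

    def test_reeig_clamps_small_eigenvalues(self):
        out = reeig_forward(np.diag([1.0, 1e-8]), epsilon=1e-4)
        np.testing.assert_allclose(out, np.diag([1.0, 1e-4]), atol=1e-12)

    def test_reeig_identity_above_floor(self, spd_factory):
        S = spd_factory(5)
        np.testing.assert_allclose(reeig_forward(S, 1e-4), S, atol=1e-10)

    def test_reeig_idempotent(self, rng):
        S = np.diag(rng.uniform(-1, 1, 6))
        once = reeig_forward(S, 1e-4)
        np.testing.assert_allclose(reeig_forward(once, 1e-4), once, atol=1e-10)

    def test_logeig_matches_matrix_log(self, rng):
        for _ in range(10):
            S = random_spd(rng, 6)
            np.testing.assert_allclose(logeig_forward(S), matrix_log(S), atol=1e-10)

    def test_spd_preserved_through_block(self, rng):
        net = SPDNet(6, bimap_dims=(4,), seed=1)
        S = spd_batch(rng, 100, 6)
        out = reeig_forward(bimap_forward(S, net.W[0]), net.reeig_eps)
        assert np.linalg.eigvalsh(out).min() >= net.reeig_eps - 1e-12


class TestForward:
    def test_probabilities_on_simplex(self, rng):
        net = SPDNet(6, bimap_dims=(4, 3), seed=2)
        p = net.forward(spd_batch(rng, 8, 6))
        assert np.all(p > 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_eval_mode_deterministic(self, rng):
        net = SPDNet(6, bimap_dims=(4,), seed=3)
        S = spd_batch(rng, 4, 6)
        np.testing.assert_array_equal(net.forward(S), net.forward(S))

    def test_zero_head_gives_uniform(self, rng):
        net = SPDNet(6, bimap_dims=(4,), n_classes=3, seed=4)
        net.fc_W[:] = 0.0
        net.fc_b[:] = 0.0
        p = net.forward(random_spd(rng, 6))
        np.testing.assert_allclose(p, 1.0 / 3.0, atol=1e-12)

    def test_nonincreasing_dims_enforced(self):
        with pytest.raises(ConfigError):
            SPDNet(6, bimap_dims=(6, 4))

    def test_default_dims_for_small_inputs(self):
        assert default_bimap_dims(8) == (6, 4)


class TestGradients:
    def test_analytic_matches_finite_differences(self, rng):
        """Backprop through BiMap/ReEig/LogEig/head vs central differences."""
        n, d = 5, 4
        S = spd_batch(rng, n, d)
        y = rng.integers(0, 3, size=n)
        net = SPDNet(d, bimap_dims=(3, 2), n_classes=3, dropout_p=0.0, seed=7)
        wd = 1e-4
        _, grads = net.loss_and_grads(S, y, weight_decay=wd)
        eps = 1e-6

        def numeric(param_get, param_set, shape):
            g = np.zeros(shape)
            base = param_get().copy()
            for idx in np.ndindex(*shape):
                for sign in (1, -1):
                    p = base.copy()
                    p[idx] += sign * eps
                    param_set(p)
                    if sign == 1:
                        lp = net.loss(S, y, wd)
                    else:
                        lm = net.loss(S, y, wd)
                g[idx] = (lp - lm) / (2 * eps)
            param_set(base)
            return g

        for k in range(2):
            ng = numeric(
                lambda k=k: net.W[k],
                lambda p, k=k: net.W.__setitem__(k, p),
                net.W[k].shape,
            )
            rel = np.max(np.abs(ng - grads["W"][k])) / np.max(np.abs(ng))
            assert rel < 1e-4
        ng = numeric(lambda: net.fc_W, lambda p: setattr(net, "fc_W", p), net.fc_W.shape)
        assert np.max(np.abs(ng - grads["fc_W"])) / np.max(np.abs(ng)) < 1e-4
        ng = numeric(lambda: net.fc_b, lambda p: setattr(net, "fc_b", p), net.fc_b.shape)
        assert np.max(np.abs(ng - grads["fc_b"])) / np.max(np.abs(ng)) < 1e-4


def separable_spd_classes(rng, n_per_class=70, d=8):
    """Three SPD classes built from distinct rank-structure prototypes."""
    protos = [random_spd(rng, d, scale=0.5) for _ in range(3)]
    S, y = [], []
    for k, P in enumerate(protos):
        for _ in range(n_per_class):
            E = rng.standard_normal((d, d)) * 0.1
            S.append(P + E @ E.T)
            y.append(k)
    order = rng.permutation(len(y))
    return np.array(S)[order], np.array(y)[order]


class TestTraining:
    def test_orthonormality_kept_and_loss_finite(self, rng):
        S, y = separable_spd_classes(rng)
        net = SPDNet(8, bimap_dims=(6, 4), seed=5)
        cfg = TrainConfig(max_epochs=5, batch_size=64, seed=5)
        history = net.fit(S, y, cfg)
        assert net.orthonormality_error() < 1e-6
        assert all(np.isfinite(h["loss"]) for h in history)

    def test_training_separates_easy_planted_classes(self):
        """Strong planted coupling (0.9) at low noise is linearly learnable."""
        from neurospd import SyntheticSpec, generate_dataset
        from neurospd.connectivity import connectivity_matrices
        from neurospd.graph import spd_stack

        spec = SyntheticSpec(
            n_channels=8,
            n_trials_per_class=1,
            epochs_per_trial=70,
            coupling_strength=0.9,
            noise_sd=0.1,
            seed=21,
        )
        ep = generate_dataset(spec)
        S = spd_stack(connectivity_matrices(ep, "plv"), kind="plv")
        net = SPDNet(8, bimap_dims=(6, 4), seed=6)
        net.fit(S, ep.labels, TrainConfig(max_epochs=100, batch_size=64, seed=6))
        assert net.history[-1]["train_acc"] >= 0.95

    def test_fixed_seed_reproducible(self, rng):
        S, y = separable_spd_classes(rng)
        cfg = TrainConfig(max_epochs=3, seed=9)
        nets = []
        for _ in range(2):
            net = SPDNet(8, bimap_dims=(6, 4), seed=9)
            net.fit(S, y, cfg)
            nets.append(net)
        for W1, W2 in zip(nets[0].W, nets[1].W):
            np.testing.assert_array_equal(W1, W2)
        np.testing.assert_array_equal(nets[0].fc_W, nets[1].fc_W)

    def test_non_spd_training_example_rejected(self, rng):
        S, y = separable_spd_classes(rng)
        S[3] = np.diag(np.arange(8.0) - 1)  # indefinite
        net = SPDNet(8, bimap_dims=(6, 4), seed=5)
        with pytest.raises(DataError, match="not SPD"):
            net.fit(S, y, TrainConfig(max_epochs=1, seed=5))

    def test_checkpoint_round_trip(self, rng, tmp_path):
        S, y = separable_spd_classes(rng, n_per_class=25)
        net = SPDNet(8, bimap_dims=(6, 4), seed=5, kind="plv")
        net.fit(S, y, TrainConfig(max_epochs=2, batch_size=32, seed=5))
        path = str(tmp_path / "model.npz")
        net.save(path)
        loaded = SPDNet.load(path)
        np.testing.assert_array_equal(loaded.predict_proba(S[:5]), net.predict_proba(S[:5]))
        assert loaded.kind == "plv"
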