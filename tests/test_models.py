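"""Recurrent core: decay gates, imputation, cell algebra, training loop."""

import numpy as np
import pytest

from conftest import make_tensor
from wardwatch.models.core import (Batch, bce_loss_and_grads, cell_step,
                                   forward, forward_stay, impute_input,
                                   init_params, input_decay, pack_params,
                                   sigmoid, tensors_to_batch, unpack_params)
from wardwatch.models.training import (EarlyStopper, TrainConfig, fine_tune,
                                       predict, predict_trajectories, train)


class TestInputDecay:
    def test_zero_elapsed_zero_bias_gives_one(self):
        assert input_decay(np.zeros(3), np.ones(3), np.zeros(3)) == pytest.approx(1.0)

    def test_closed_form_half_life(self):
        g = input_decay(np.array([np.log(2)]), np.array([1.0]), np.array([0.0]))
        assert g[0] == pytest.approx(0.5, abs=1e-12)

    def test_negative_preactivation_clamps_to_one(self):
        g = input_decay(np.array([2.0]), np.array([-1.0]), np.array([0.0]))
        assert g[0] == 1.0

    def test_matches_scalar_evaluation(self):
        rng = np.random.default_rng(0)
        w, b, d = rng.normal(size=(3, 8))
        d = np.abs(d)
        g = input_decay(d, w, b)
        for i in range(8):
            expect = np.exp(-max(0.0, w[i] * d[i] + b[i]))
            assert abs(g[i] - expect) < 1e-12


class TestImputeInput:
    def test_observed_passthrough(self):
        x = impute_input(np.array([7.0]), np.array([1.0]), np.array([0.2]),
                         np.array([1.0]), np.array([1.0]), np.array([0.0]), None,
                         no_history="global_mean")
        assert x[0] == 7.0

    def test_full_decay_keeps_last_observation(self):
        x = impute_input(np.array([0.0]), np.array([0.0]), np.array([1.0]),
                         np.array([2.0]), np.array([1.0]), np.array([9.0]), None,
                         no_history="global_mean")
        assert x[0] == 2.0

    def test_partial_decay_blends_toward_mean(self):
        x = impute_input(np.array([0.0]), np.array([0.0]), np.array([0.3]),
                         np.array([2.0]), np.array([1.0]), np.array([0.0]), None,
                         no_history="global_mean")
        assert x[0] == pytest.approx(0.6)

    def test_no_history_strategies(self):
        args = (np.array([0.0]), np.array([0.0]), np.array([0.5]),
                np.array([0.0]), np.array([0.0]), np.array([2.0]))
        trainable = impute_input(*args, np.array([4.0]), no_history="trainable")
        assert trainable[0] == pytest.approx(0.5 * 4.0 + 0.5 * 2.0)
        mean = impute_input(*args, None, no_history="global_mean")
        assert mean[0] == pytest.approx(2.0)
        with pytest.raises(ValueError, match="fully observed"):
            impute_input(*args, None, no_history=None)


class TestCellStep:
    def _tiny_params(self):
        # one hidden unit, two channels: every matrix is a scalar or 2-vector
        return {"Wz": np.array([[0.3], [-0.2]]), "Uz": np.array([[0.1]]),
                "Vz": np.array([[0.05], [0.0]]), "bz": np.array([0.1]),
                "Wr": np.array([[0.2], [0.4]]), "Ur": np.array([[-0.3]]),
                "Vr": np.array([[0.0], [0.1]]), "br": np.array([-0.1]),
                "Wc": np.array([[0.5], [0.2]]), "Uc": np.array([[0.6]]),
                "Vc": np.array([[0.1], [-0.1]]), "bc": np.array([0.0])}

    def test_matches_pencil_and_paper_recurrence(self):
        import math
        p = self._tiny_params()
        xhat = np.array([[0.5, -1.0]])
        m = np.array([[1.0, 0.0]])
        gh = np.array([[0.8]])
        h_prev = np.array([[0.4]])
        h = cell_step(p, xhat, m, gh, h_prev)
        hh = 0.8 * 0.4
        z = 1 / (1 + math.exp(-(0.5 * 0.3 + -1.0 * -0.2 + hh * 0.1 + 1.0 * 0.05 + 0.1)))
        r = 1 / (1 + math.exp(-(0.5 * 0.2 + -1.0 * 0.4 + hh * -0.3 + 0.0 * 0.1 - 0.1)))
        c = math.tanh(0.5 * 0.5 + -1.0 * 0.2 + r * hh * 0.6 + 1.0 * 0.1)
        assert h[0, 0] == pytest.approx((1 - z) * hh + z * c, abs=1e-12)

    def test_decayed_zero_state_stays_zero_in_gate_input(self):
        p = self._tiny_params()
        h = cell_step(p, np.zeros((1, 2)), np.zeros((1, 2)), np.array([[0.123]]),
                      np.zeros((1, 1)))
        h_ref = cell_step(p, np.zeros((1, 2)), np.zeros((1, 2)), np.array([[0.9]]),
                          np.zeros((1, 1)))
        assert h[0, 0] == h_ref[0, 0]  # decay of a zero state is zero

    def test_nonfinite_inputs_error(self):
        p = self._tiny_params()
        with pytest.raises(ValueError, match="non-finite"):
            cell_step(p, np.array([[np.nan, 0.0]]), np.zeros((1, 2)),
                      np.ones((1, 1)), np.zeros((1, 1)))


def _random_batch(rng, B=6, T=5, D=4, dense=False):
    M = (rng.uniform(size=(B, T, D)) < 0.7).astype(float)
    if dense:
        M = np.ones((B, T, D))
    X = rng.normal(size=(B, T, D)) * M
    Delta = np.zeros((B, T, D))
    for t in range(1, T):
        Delta[:, t] = np.where(M[:, t - 1] == 1, 1.0, Delta[:, t - 1] + 1.0)
    static = rng.normal(size=(B, 2))
    lengths = rng.integers(1, T + 1, size=B)
    lengths[0] = T
    y = (rng.uniform(size=B) < 0.5).astype(float)
    y[:2] = [0, 1]
    return Batch(X, M, Delta, static, lengths, y)


class TestGRUReduction:
    @pytest.mark.parametrize("variant", ["gru_d", "gru_d_pp"])
    def test_reduces_to_plain_gru_when_fully_observed(self, variant):
        rng = np.random.default_rng(42)
        for rep in range(3):
            p = init_params(variant, 4, hidden=8, seed=rep)
            for k in p:
                p[k] = rng.normal(0, 0.5, p[k].shape)
            # pin decays to one and silence the mask pathway
            for k in ("w_gx", "b_gx", "b_gh"):
                p[k][...] = 0.0
            p["W_gh"][...] = 0.0
            gru = {k: v for k, v in p.items()
                   if not k.startswith(("V", "w_g", "b_g", "W_g")) and k != "x0"}
            batch = _random_batch(rng, dense=True)
            for k in ("Vz", "Vr", "Vc"):
                p[k][...] = 0.0
            la, _ = forward(p, batch, variant)
            lb, _ = forward(gru, batch, "gru")
            assert np.max(np.abs(la - lb)) < 1e-10


class TestForward:
    def test_zero_weights_give_sigmoid_of_bias(self):
        t = make_tensor(np.array([[0.5, 1.0], [np.nan, 2.0]]))
        p = init_params("gru_d_pp", 2, hidden=4, seed=0)
        for k in p:
            p[k][...] = 0.0
        p["b_out"][...] = 0.7
        risk, traj = forward_stay(p, t, "gru_d_pp")
        assert risk == pytest.approx(sigmoid(np.array([0.7]))[0])

    def test_trajectory_ends_at_risk(self):
        t = make_tensor(np.array([[0.5, 1.0], [np.nan, 2.0], [1.0, np.nan]]))
        p = init_params("gru_d_pp", 2, hidden=4, seed=1)
        risk, traj = forward_stay(p, t, "gru_d_pp")
        assert len(traj) == 3 and traj[-1] == pytest.approx(risk)

    def test_forward_matches_manual_cell_composition(self):
        """The batched forward equals a step-by-step composition of the
        audited primitives (input_decay + impute_input + cell_step)."""
        rng = np.random.default_rng(7)
        D, H = 3, 5
        p = init_params("gru_d_pp", D, hidden=H, seed=3)
        for k in p:
            p[k] = rng.normal(0, 0.4, p[k].shape)
        X = np.array([[0.5, np.nan, 1.0], [np.nan, np.nan, -1.0],
                      [0.2, 0.3, np.nan]])
        t = make_tensor(X, static=(0.3, 1.0))
        xbar = np.zeros(D)
        h = np.zeros((1, H))
        x_last = np.zeros(D)
        hist = np.zeros(D)
        manual = []
        for day in range(3):
            m = t.M[day]
            x = np.nan_to_num(t.X[day])
            d = t.Delta[day]
            gx = input_decay(d, p["w_gx"], p["b_gx"])
            gh = np.exp(-np.maximum(0.0, d @ p["W_gh"] + p["b_gh"]))
            xhat = impute_input(x, m, gx, x_last, hist, xbar, p["x0"],
                                no_history="trainable")
            h = cell_step(p, xhat[None, :], m[None, :], gh[None, :], h)
            manual.append(sigmoid(h @ p["w_out"] + t.static @ p["w_static"]
                                  + p["b_out"])[0])
            x_last = np.where(m == 1, x, x_last)
            hist = np.maximum(hist, m)
        risk, traj = forward_stay(p, t, "gru_d_pp")
        assert np.allclose(traj, np.array(manual).ravel(), atol=1e-12)

    def test_empty_time_axis_errors(self):
        p = init_params("gru", 2, hidden=4, seed=0)
        batch = Batch(np.zeros((1, 0, 2)), np.zeros((1, 0, 2)),
                      np.zeros((1, 0, 2)), np.zeros((1, 2)),
                      np.array([0]), np.array([0.0]))
        with pytest.raises(ValueError, match="empty time axis"):
            forward(p, batch, "gru")

    def test_prefix_prediction_ignores_the_future(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(5, 3))
        X[4] = 99.0  # absurd final day
        t_full = make_tensor(X.copy())
        X2 = X.copy()
        X2[4] = -99.0
        t_pert = make_tensor(X2)
        p = init_params("gru_d_pp", 3, hidden=6, seed=2)
        _, traj_a = forward_stay(p, t_full, "gru_d_pp")
        _, traj_b = forward_stay(p, t_pert, "gru_d_pp")
        assert np.array_equal(traj_a[:4], traj_b[:4])
        assert traj_a[4] != traj_b[4]


class TestGradients:
    @pytest.mark.parametrize("variant", ["gru", "gru_d_pp"])
    def test_analytic_matches_central_differences(self, variant):
        rng = np.random.default_rng(5)
        p = init_params(variant, 3, hidden=4, seed=9)
        for k in p:
            p[k] = rng.normal(0, 0.4, p[k].shape)
        batch = _random_batch(rng, B=4, T=3, D=3,
                              dense=variant in ("rnn", "gru"))
        xbar = rng.normal(0, 0.3, 3)
        loss, g = bce_loss_and_grads(p, batch, variant, xbar)
        vec, shapes = pack_params(p)
        gvec, _ = pack_params(g)
        num = np.zeros_like(vec)
        eps = 1e-6
        for i in range(len(vec)):
            up, dn = vec.copy(), vec.copy()
            up[i] += eps
            dn[i] -= eps
            lu, _ = bce_loss_and_grads(unpack_params(up, shapes), batch, variant,
                                       xbar, want_grads=False)
            ld, _ = bce_loss_and_grads(unpack_params(dn, shapes), batch, variant,
                                       xbar, want_grads=False)
            num[i] = (lu - ld) / (2 * eps)
        # floor keeps finite-difference round-off on near-zero coordinates
        # from masquerading as relative error
        rel = np.abs(gvec - num) / np.maximum(1e-6, np.abs(gvec) + np.abs(num))
        assert rel.max() < 1e-4


class TestEarlyStopper:
    def test_strict_improvement_never_stops(self):
        s = EarlyStopper(patience=3)
        for epoch, loss in enumerate([1.0, 0.9, 0.8, 0.7, 0.6]):
            assert not s.update(epoch, loss)
        assert s.best_epoch == 4

    def test_stops_after_patience_stale_epochs(self):
        s = EarlyStopper(patience=3)
        flags = [s.update(e, l) for e, l in
                 enumerate([1.0, 0.5, 0.6, 0.6, 0.7])]
        assert flags == [False, False, False, False, True]
        assert s.best_epoch == 1

    def test_plateau_counts_as_stale(self):
        s = EarlyStopper(patience=2)
        assert not s.update(0, 1.0)
        assert not s.update(1, 1.0)
        assert s.update(2, 1.0)


def _toy_tensors(rng, n=200, d=2, separation=3.0):
    tensors = []
    for i in range(n):
        y = i % 2
        X = rng.normal(size=(3, d)) + (separation if y else -separation)
        tensors.append(make_tensor(X, static=(0.0, 0.0), label=y,
                                   stay_id=f"t{i}"))
    return tensors


class TestTraining:
    def test_learns_separable_toy_problem(self):
        rng = np.random.default_rng(0)
        tensors = _toy_tensors(rng)
        from wardwatch.evaluation import auroc
        params, log = train("gru_d_pp", tensors,
                            TrainConfig(max_epochs=200, seed=0))
        scores = predict(params, "gru_d_pp", tensors)
        labels = [t.label for t in tensors]
        assert auroc(scores, labels) >= 0.99

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        tensors = _toy_tensors(rng, n=60, separation=1.0)
        cfg = TrainConfig(max_epochs=5, seed=4)
        p1, _ = train("gru_d", tensors, cfg)
        p2, _ = train("gru_d", tensors, cfg)
        for k in p1:
            assert np.array_equal(p1[k], p2[k])

    def test_single_class_data_errors(self):
        rng = np.random.default_rng(2)
        tensors = [make_tensor(rng.normal(size=(2, 2)), label=1, stay_id=str(i))
                   for i in range(20)]
        with pytest.raises(ValueError, match="both classes"):
            train("gru", tensors, TrainConfig(seed=0))

    def test_runs_to_max_epochs_without_stopping_signal(self):
        rng = np.random.default_rng(3)
        tensors = _toy_tensors(rng, n=60, separation=1.0)
        _, log = train("gru_d", tensors, TrainConfig(max_epochs=6, seed=0))
        assert log.stopped_epoch == 5  # patience 20 never fires in 6 epochs

    def test_shuffled_labels_give_chance_validation_auroc(self):
        """No memorization leaks through the selection split."""
        from wardwatch.evaluation import auroc
        rng = np.random.default_rng(4)
        tensors = _toy_tensors(rng, n=400, separation=1.0)
        labels = np.array([t.label for t in tensors])
        rng.shuffle(labels)
        for t, y in zip(tensors, labels):
            t.label = int(y)
        held_out = _toy_tensors(np.random.default_rng(5), n=300, separation=1.0)
        rng2 = np.random.default_rng(7)
        for t in held_out:
            t.label = int(rng2.integers(0, 2))
        params, _ = train("gru", tensors, TrainConfig(max_epochs=40, seed=0))
        scores = predict(params, "gru", held_out)
        a = auroc(scores, [t.label for t in held_out])
        assert 0.4 <= a <= 0.6


class TestFineTune:
    def _site(self, rng, n=200):
        return _toy_tensors(rng, n=n, separation=1.2)

    def test_fraction_zero_is_zero_shot(self):
        rng = np.random.default_rng(8)
        tensors = self._site(rng)
        pre, _ = train("gru", self._site(np.random.default_rng(9)),
                       TrainConfig(max_epochs=10, seed=0))
        out = fine_tune(pre, "gru", tensors, [0.0], TrainConfig(seed=1))
        assert out[0.0]["params"] is pre

    def test_training_subsets_are_nested(self):
        rng = np.random.default_rng(10)
        tensors = self._site(rng, n=300)
        pre, _ = train("gru", self._site(np.random.default_rng(11)),
                       TrainConfig(max_epochs=5, seed=0))
        out = fine_tune(pre, "gru", tensors, [0.1, 0.3, 0.5],
                        TrainConfig(max_epochs=3, seed=2))
        ids = {f: set(out[f]["train_ids"]) for f in (0.1, 0.3, 0.5)}
        assert ids[0.1] < ids[0.3] < ids[0.5]

    def test_oversized_fractions_error(self):
        rng = np.random.default_rng(12)
        tensors = self._site(rng, n=40)
        pre = init_params("gru", 2, hidden=4, seed=0)
        with pytest.raises(ValueError, match="exceed"):
            fine_tune(pre, "gru", tensors, [0.6], TrainConfig(seed=0))
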