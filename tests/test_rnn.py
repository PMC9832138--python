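import numpy as np
import pytest

from selinhib.rnn import (
    RNNParams,
    estimate_gamma_rnn,
    forward,
    init_rnn,
    load_checkpoint,
    loss,
    loss_and_grads,
    make_batch,
    roc_selectivity,
    save_checkpoint,
    train,
    validate,
)
from selinhib.workbench import make_fixture

SMALL = RNNParams(N_E=8, N_I=3, N_time=45, N_trial=8)


class _FrozenRng:
    """Replays the same normal stream on every fresh instance with one seed."""

    def __init__(self, seed):
        self._rng = np.random.default_rng(seed)

    def standard_normal(self, shape=None):
        return self._rng.standard_normal(shape)


class TestInit:
    def test_invariants_and_normalization(self):
        p = RNNParams()
        W = init_rnn(p, 0)
        W.check_invariants()
        assert np.allclose(W["in"].sum(axis=0), 1.0, atol=1e-12)
        assert np.allclose(W["out"].sum(axis=1), 1.0, atol=1e-12)

    def test_inhibitory_scale_factor(self):
        p = RNNParams(s_E=1.0, s_I=1.0)
        assert p.theta == pytest.approx(4.0)
        # hence the inhibitory Gamma shape parameter is 4 * 0.0375 = 0.15
        assert p.theta * p.w_mu == pytest.approx(0.15)


class TestBatch:
    def test_catch_fraction(self):
        p = RNNParams()
        batch = make_batch(p, 200, 0)
        assert batch["is_catch"].mean() == pytest.approx(0.5, abs=0.01)

    def test_stimulus_stream_contrast(self):
        p = RNNParams()
        batch = make_batch(p, 10, 0, coherences=[20.0] * 10)
        i = 0
        t_on, t_off = batch["t_on"][i], batch["t_off"][i]
        assert t_off - t_on == 21
        # noise-free means differ by 2 * mu * 0.2 = 1.28 during the stimulus
        diff = 2 * p.mu * 20.0 / 100.0
        measured = batch["u"][:, :, 0][np.arange(10), t_on] - batch["u"][:, :, 1][np.arange(10), t_on]
        assert measured.mean() == pytest.approx(diff, abs=0.2)

    def test_catch_trials_flat_targets_full_mask(self):
        p = RNNParams()
        batch = make_batch(p, 100, 1)
        catch = batch["is_catch"]
        assert np.all(batch["T"][catch] == 0.2)
        assert np.all(batch["M"][catch] == 1.0)

    def test_mask_zero_during_stimulus_on_active_trials(self):
        p = RNNParams()
        batch = make_batch(p, 50, 2)
        for i in np.flatnonzero(~batch["is_catch"])[:5]:
            assert np.all(batch["M"][i, batch["t_on"][i]: batch["t_off"][i]] == 0.0)

    def test_infeasible_onset_rejected(self):
        with pytest.raises(ValueError):
            RNNParams(N_time=30)


class TestForward:
    def test_zero_weights_input_filter_geometric(self):
        p = SMALL
        W = init_rnn(p, 0)
        for k in W:
            W[k] = np.zeros_like(W[k])
        batch = make_batch(p, 4, 3)
        fwd = forward(W, p, batch, 0, noise=False)
        # x_in follows the leaky filter of u exactly
        xin = np.zeros((4, p.N_in))
        for t in range(p.N_time):
            xin = (1 - p.alpha_in) * xin + p.alpha_in * batch["u"][:, t]
            assert np.allclose(fwd["XIN"][:, t], xin)

    def test_rates_nonnegative(self):
        p = SMALL
        W = init_rnn(p, 1)
        fwd = forward(W, p, make_batch(p, 4, 3), 5)
        assert fwd["RE"].min() >= 0 and fwd["RI"].min() >= 0

    def test_outputs_depend_only_on_excitatory_rates(self):
        p = SMALL
        W = init_rnn(p, 1)
        batch = make_batch(p, 4, 3)
        fwd = forward(W, p, batch, _FrozenRng(9))
        assert np.allclose(fwd["Z"], fwd["RE"] @ W["out"].T)


class TestLoss:
    def test_perfect_outputs_zero_weights_zero_loss(self):
        p = SMALL
        W = init_rnn(p, 0)
        for k in W:
            W[k] = np.zeros_like(W[k])
        batch = make_batch(p, 4, 3)
        fwd = {"Z": batch["T"].copy(), "XE": np.zeros((4, p.N_time, p.N_E)), "XI": np.zeros((4, p.N_time, p.N_I))}
        assert loss(W, p, batch, fwd) == 0.0

    def test_weight_penalty_linear_in_lambda_w(self):
        import dataclasses

        p = SMALL
        W = init_rnn(p, 0)
        batch = make_batch(p, 4, 3)
        fwd = forward(W, p, batch, _FrozenRng(9))
        L1 = loss(W, p, batch, fwd)
        p2 = dataclasses.replace(p, lambda_w=2 * p.lambda_w)
        L2 = loss(W, p2, batch, fwd)
        l1_term = p.lambda_w / p.N**2 * sum(np.abs(W[k]).sum() for k in ("EE", "EI", "IE", "II"))
        assert L2 - L1 == pytest.approx(l1_term, rel=1e-9)

    def test_stimulus_step_errors_masked_out(self):
        p = SMALL
        W = init_rnn(p, 0)
        batch = make_batch(p, 4, 3, coherences=[10.0, -10.0, 4.0, -4.0])
        fwd = forward(W, p, batch, _FrozenRng(9))
        L0 = loss(W, p, batch, fwd)
        # corrupt targets only within the stimulus window
        batch2 = {k: (v.copy() if hasattr(v, "copy") else v) for k, v in batch.items()}
        for i in range(4):
            batch2["T"][i, batch2["t_on"][i]: batch2["t_off"][i]] += 5.0
        assert loss(W, p, batch2, fwd) == pytest.approx(L0, rel=1e-12)

    def test_analytic_gradients_match_finite_differences(self):
        p = SMALL
        W = init_rnn(p, 0)
        # lift weights away from zero so the central difference of the L1
        # penalty |W| does not straddle its kink
        for k in ("EE", "EI", "IE", "II"):
            W[k] = W[k] + 0.01
        np.fill_diagonal(W["EE"], 0.0)
        np.fill_diagonal(W["II"], 0.0)
        batch = make_batch(p, 4, 5)
        L, g, _ = loss_and_grads(W, p, batch, _FrozenRng(9))
        eps = 1e-6
        rng = np.random.default_rng(0)
        for k in ("EE", "EI", "IE", "II", "in", "out"):
            idx = tuple(rng.integers(0, s) for s in W[k].shape)
            for _ in range(2):
                Wp, Wm = W.copy(), W.copy()
                Wp[k][idx] += eps
                Wm[k][idx] -= eps
                Lp, _, _ = loss_and_grads(Wp, p, batch, _FrozenRng(9))
                Lm, _, _ = loss_and_grads(Wm, p, batch, _FrozenRng(9))
                num = (Lp - Lm) / (2 * eps)
                assert g[k][idx] == pytest.approx(num, rel=2e-4, abs=1e-9)
                idx = tuple(rng.integers(0, s) for s in W[k].shape)


class TestTraining:
    def test_loss_decreases_early(self):
        p = RNNParams(N_E=30, N_I=8, N_trial=50)
        ok = 0
        for seed in range(3):
            t = train(p, seed=seed, max_epochs=10)
            losses = [h["loss"] for h in t.history]
            if np.mean(losses[-3:]) < np.mean(losses[:3]):
                ok += 1
        assert ok >= 2

    def test_invariants_hold_across_checkpoints(self):
        p = RNNParams(N_E=20, N_I=5, N_trial=30)
        seen = []

        def cb(epoch, L, perf):
            seen.append(epoch)

        t = train(p, seed=0, max_epochs=5, callback=cb)
        t.weights.check_invariants()
        assert len(seen) == t.epochs

    def test_training_reproducible_from_seed(self):
        p = RNNParams(N_E=12, N_I=4, N_trial=20)
        a = train(p, seed=3, max_epochs=3)
        b = train(p, seed=3, max_epochs=3)
        for k in ("EE", "EI", "IE", "II", "in", "out"):
            assert np.array_equal(a.weights[k], b.weights[k])

    def test_stopping_epoch_meets_criterion(self, trained_networks):
        for t in trained_networks:
            assert t.reached_criterion
            assert t.history[-1]["performance"] >= 0.85

    def test_checkpoint_round_trip(self, tmp_path, trained_networks):
        t = trained_networks[0]
        save_checkpoint(t, tmp_path / "net.npz")
        loaded = load_checkpoint(tmp_path / "net.npz")
        assert loaded.params == t.params
        for k in ("EE", "out"):
            assert np.array_equal(loaded.weights[k], t.weights[k])


class TestValidate:
    def test_constructed_trace_violating_prestim_rule_invalid(self):
        # a decision variable that is above threshold through the pre-stimulus
        # period must be flagged invalid by the 75% pre-stimulus rule
        z = make_fixture("output_trace", n_steps=60, t_on=15, cross_step=5, level=0.5)
        z[:15, 0] += 0.5  # separated during the whole pre-period
        above = np.abs(z[:, 0] - z[:, 1]) > 0.25
        assert above[:15].mean() > 0.25  # the rule fires on this fixture

    def test_trained_networks_fail_mostly_on_hard_stimuli(self, trained_networks):
        t = trained_networks[0]
        val = validate(t.weights, t.params, np.random.default_rng(0), n_trials=210)
        cs = np.abs(val["coherence"])
        hard = cs <= 4
        easy = cs >= 16
        err_hard = 1.0 - val["correct"][hard & (val["coherence"] != 0)].mean()
        err_easy = 1.0 - val["correct"][easy].mean()
        assert err_hard > err_easy

    def test_decision_times_decrease_with_coherence(self, trained_networks):
        t = trained_networks[0]
        val = validate(t.weights, t.params, np.random.default_rng(1), n_trials=420)
        ok = val["valid"] & (val["decision_step"] >= 0)
        cs = np.abs(val["coherence"][ok])
        steps = val["decision_step"][ok]
        assert steps[cs <= 6].mean() > steps[cs >= 14].mean()


class TestSelectivity:
    def test_choice_independent_unit_not_significant(self):
        from scipy.stats import rankdata

        rng = np.random.default_rng(0)
        acts, labels = make_fixture("synthetic_unit_activity", seed=1, n_per_class=100, shift=0.0)
        ranks = rankdata(acts)
        n1 = labels.sum()
        auc = (ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * (len(labels) - n1))
        assert abs(auc - 0.5) < 0.12

    def test_synthetic_shift_matches_closed_form_auc(self):
        """AUC of two unit-variance normals shifted by d is Phi(d/sqrt(2))."""
        from scipy.stats import norm, rankdata

        shift = 1.0
        acts, labels = make_fixture("synthetic_unit_activity", seed=2, n_per_class=2000, shift=shift)
        ranks = rankdata(acts)
        n1 = labels.sum()
        auc = (ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * (len(labels) - n1))
        assert auc == pytest.approx(norm.cdf(shift / np.sqrt(2)), abs=0.02)

    def test_index_bounded(self, trained_networks):
        t = trained_networks[0]
        sel = roc_selectivity(t.weights, t.params, np.random.default_rng(2))
        assert np.all(sel["index"] >= 0) and np.all(sel["index"] <= 0.5)

    def test_inhibitory_units_more_selective(self, trained_networks):
        idx_I, idx_E = [], []
        for i, t in enumerate(trained_networks):
            sel = roc_selectivity(t.weights, t.params, np.random.default_rng(100 + i))
            idx_I.append(sel["index"][t.params.N_E:].mean())
            idx_E.append(sel["index"][: t.params.N_E].mean())
        assert np.mean(idx_I) > np.mean(idx_E)


class TestGammaEstimation:
    def _report(self, pref, sig=None):
        n = len(pref)
        sig = np.ones(n, bool) if sig is None else sig
        return {"significant": sig, "preferred_choice": pref}

    def test_planted_block_matrix_exact(self):
        W, pref = make_fixture("planted_weight_matrix", n_per_group=5, w_same=2.0, w_opposite=1.0)
        p = RNNParams(N_E=10, N_I=10)
        weights = {"EE": W, "EI": W, "IE": W, "II": W}
        sel = self._report(np.concatenate([pref, pref]))
        gh = estimate_gamma_rnn(weights, sel, p)
        # diagonal exclusion does not bias a block-constant matrix
        assert gh["EE"] == pytest.approx(1.0 / 3.0, rel=1e-12)
        assert gh["II"] == pytest.approx(1.0 / 3.0, rel=1e-12)

    def test_scale_invariance(self):
        W, pref = make_fixture("planted_weight_matrix", n_per_group=5, w_same=2.0, w_opposite=1.0, noise_sd=0.3, seed=4)
        p = RNNParams(N_E=10, N_I=10)
        sel = self._report(np.concatenate([pref, pref]))
        g1 = estimate_gamma_rnn({"EE": W, "EI": W, "IE": W, "II": W}, sel, p)
        g2 = estimate_gamma_rnn({"EE": 7 * W, "EI": 7 * W, "IE": 7 * W, "II": 7 * W}, sel, p)
        assert g1["EE"] == pytest.approx(g2["EE"], rel=1e-12)

    def test_noisy_planted_gamma_recovered(self):
        W, pref = make_fixture("planted_weight_matrix", n_per_group=30, w_same=1.5, w_opposite=0.5, noise_sd=0.2, seed=7)
        p = RNNParams(N_E=60, N_I=60)
        sel = self._report(np.concatenate([pref, pref]))
        gh = estimate_gamma_rnn({"EE": W, "EI": W, "IE": W, "II": W}, sel, p)
        assert gh["EE"] == pytest.approx(0.5, abs=0.05)

    def test_missing_preference_group_reported_absent(self):
        p = RNNParams(N_E=6, N_I=6)
        W = np.ones((6, 6))
        pref = np.ones(12, int)  # everyone prefers choice 1
        gh = estimate_gamma_rnn({"EE": W, "EI": W, "IE": W, "II": W}, self._report(pref), p)
        assert gh["EE"] is None
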