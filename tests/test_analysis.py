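import numpy as np
import pytest
from scipy.optimize import least_squares

from selinhib import CircuitParams, StimulusSpec, derive_couplings, find_fixed_points, linearize
from selinhib.analysis import bifurcation_sweep, classify_circuit, label_fixed_points
from selinhib.meanfield import drift


def _stim0(params):
    return StimulusSpec.from_schedule(params.schedule, coherence_c=0.0)


class TestFindFixedPoints:
    def test_reference_circuit_census(self, params):
        unstim = find_fixed_points(params)
        stim = find_fixed_points(params, stim=_stim0(params))
        assert len(unstim) == 5
        assert len(stim) == 3

    def test_residuals_verified_by_substitution(self, params, couplings):
        for stim in (None, _stim0(params)):
            for f in find_fixed_points(params, stim=stim):
                Iext = (0.0, 0.0)
                if stim is not None:
                    base = params.J_AMPA_ext * stim.mu
                    Iext = (base, base)
                F1, F2 = drift(f.S[0], f.S[1], params, couplings, *Iext)
                assert max(abs(F1), abs(F2)) <= 1e-6

    def test_mirror_closure_at_zero_coherence(self, params):
        for stim in (None, _stim0(params)):
            fps = find_fixed_points(params, stim=stim)
            pts = np.array([f.S for f in fps])
            for pt in pts:
                d = np.hypot(pts[:, 0] - pt[1], pts[:, 1] - pt[0]).min()
                assert d < 1e-4

    def test_agrees_with_scipy_levenberg_marquardt(self, params, couplings):
        """Independent oracle: scipy LM from the same multistart grid."""

        def F(S):
            return drift(S[0], S[1], params, couplings)

        roots = []
        for s1 in np.linspace(0, 1, 9):
            for s2 in np.linspace(0, 1, 9):
                r = least_squares(lambda S: np.array(F(S), dtype=float), [s1, s2], method="lm", xtol=1e-13, ftol=1e-13)
                fx = np.abs(np.array(F(r.x), dtype=float)).max()
                if fx < 1e-6 and np.all(r.x > -1e-6) and np.all(r.x < 1 + 1e-6):
                    if not any(np.hypot(*(r.x - q)) < 1e-4 for q in roots):
                        roots.append(np.clip(r.x, 0, 1))
        mine = np.array([f.S for f in find_fixed_points(params)])
        assert len(roots) == len(mine)
        for q in roots:
            assert np.hypot(*(mine - q).T).min() < 1e-5

    def test_degenerate_circuit_returns_short_list_not_error(self, params):
        # strongly ipsispecific: only the symmetric attractor survives
        fps = find_fixed_points(params.with_specificity(gamma_IE=0.8))
        assert 1 <= len(fps) < 5


class TestLinearize:
    def test_jacobian_matches_finite_differences(self, params, couplings):
        rng = np.random.default_rng(0)
        h = 1e-6
        for _ in range(100):
            S = rng.uniform(0.02, 0.95, 2)
            from selinhib.analysis import _field_and_jac

            F1, F2, J11, J12, J21, J22 = _field_and_jac(S[0], S[1], couplings.alpha1, couplings.alpha2, couplings.I0_1, 0.0, 0.0, params)
            num = np.empty((2, 2))
            for j in range(2):
                Sp, Sm = S.copy(), S.copy()
                Sp[j] += h
                Sm[j] -= h
                Fp = drift(Sp[0], Sp[1], params, couplings)
                Fm = drift(Sm[0], Sm[1], params, couplings)
                num[0, j] = (Fp[0] - Fm[0]) / (2 * h)
                num[1, j] = (Fp[1] - Fm[1]) / (2 * h)
            J = np.array([[J11, J12], [J21, J22]], dtype=float)
            assert np.allclose(J, num, atol=1e-5, rtol=1e-5)

    def test_stimulated_saddle_competition_direction(self, params, couplings):
        stim = _stim0(params)
        saddle = [f for f in find_fixed_points(params, stim=stim) if f.stability == "saddle"][0]
        J, ev, stability, tau = linearize(params, saddle.S, stim=stim)
        assert stability == "saddle"
        reals = np.array([e.real for e in ev])
        assert (reals > 0).sum() == 1
        # the unstable eigenvector is the competition direction (opposite signs)
        lam = reals.max()
        vec = np.array([J[0, 1], lam - J[0, 0]])
        assert vec[0] * vec[1] < 0 or np.sign(J[0, 1]) != np.sign(lam - J[0, 0])
        w = np.linalg.eig(J)[1][:, np.argmax(np.linalg.eig(J)[0].real)]
        assert w[0].real * w[1].real < 0

    def test_low_state_attractor_eigenvalues_negative(self, params):
        low = find_fixed_points(params)[0]
        _, ev, stability, tau = linearize(params, low.S)
        assert stability == "attractor"
        assert all(e.real < 0 for e in ev)
        assert tau is None

    def test_rejects_non_fixed_point(self, params):
        with pytest.raises(ValueError):
            linearize(params, (0.4, 0.4))

    def test_tau_slow_matches_efolding_of_separation(self, params, couplings):
        """Noiseless trajectory started slightly off the saddle along the
        unstable eigenvector grows with rate 1/tau_slow (within 10%)."""
        stim = _stim0(params)
        saddle = [f for f in find_fixed_points(params, stim=stim) if f.stability == "saddle"][0]
        J, ev, _, tau = linearize(params, saddle.S, stim=stim)
        lam, vecs = np.linalg.eig(J)
        v = vecs[:, np.argmax(lam.real)].real
        v /= np.linalg.norm(v)
        base = params.J_AMPA_ext * 40.0
        S = np.array(saddle.S) + 1e-4 * v
        dt = params.dt
        seps = []
        for _ in range(200):
            F = drift(S[0], S[1], params, couplings, base, base)
            S = S + dt * np.array(F)
            seps.append(abs(S[0] - S[1]))
        seps = np.array(seps)
        t = np.arange(1, len(seps) + 1) * dt
        # fit exponential growth rate over the early linear regime
        mask = seps < 10 * seps[0]
        rate = np.polyfit(t[mask], np.log(seps[mask]), 1)[0]
        assert rate == pytest.approx(1.0 / tau, rel=0.10)


class TestLabeling:
    def test_reference_circuit_all_flags(self, params):
        cls = classify_circuit(params)
        assert cls.is_good_decision_circuit
        assert cls.low_state_attractor and cls.wm_attractor_pair and cls.unstim_saddle_pair
        assert cls.choice_attractor_pair and cls.stim_saddle
        assert cls.n_unstim == (3, 2, 0) and cls.n_stim == (2, 1, 0)

    def test_low_gamma_EE_nonspecific_lacks_choice_states(self, params):
        p = params.with_specificity(gamma_EE=0.225, gamma_IE=0.0)
        cls = classify_circuit(p)
        assert not cls.is_good_decision_circuit
        assert not cls.choice_attractor_pair
        assert not cls.wm_attractor_pair

    def test_empty_input_all_false(self):
        cls = label_fixed_points([], [])
        assert not any(
            [cls.low_state_attractor, cls.wm_attractor_pair, cls.unstim_saddle_pair, cls.choice_attractor_pair, cls.stim_saddle, cls.is_good_decision_circuit]
        )


class TestStabilityBySimulation:
    def test_classification_agrees_with_long_run_dynamics(self, params):
        """Attractors absorb perturbed starts; saddles expel them along the
        unstable direction.  Checked on circuits sampled across motifs."""
        rng = np.random.default_rng(2)
        count = 0
        for gIE in np.linspace(-0.45, 0.08, 20):
            p = params.with_specificity(gamma_IE=float(gIE))
            c = derive_couplings(p)
            fps = find_fixed_points(p)
            for f in fps:
                S = np.array(f.S) + rng.uniform(-1, 1, 2) * 1e-4
                S0 = np.array(f.S)
                for _ in range(4000):
                    F = drift(S[0], S[1], p, c)
                    S = np.clip(S + p.dt * np.array(F), 0, 1)
                d = np.linalg.norm(S - S0)
                if f.stability == "attractor":
                    assert d < 1e-5
                else:
                    assert d > 1e-3
            count += 1
        assert count == 20


class TestBifurcationSweep:
    def test_tau_slow_increases_toward_ipsispecific(self, params):
        stim = _stim0(params)
        table, events = bifurcation_sweep(params, "gamma_IE", np.linspace(-0.2, 0.3, 21), stim=stim)
        sym_saddles = table[(table.stability == "saddle") & (np.abs(table.r1 - table.r2) < 0.1)]
        ts = sym_saddles.groupby("value").tau_slow.first().dropna()
        assert len(ts) >= 10
        assert np.all(np.diff(ts.values) > 0)

    def test_saddle_stabilizes_at_high_specificity_index(self, params):
        stim = _stim0(params)
        _, events = bifurcation_sweep(params, "gamma_IE", np.linspace(0.05, 0.2, 16), stim=stim)
        assert any(e["signature_before"][0] < e["signature_after"][0] for e in events)
        ev = events[0]
        assert ev["bracket"][1] - ev["bracket"][0] <= 1e-4

    def test_working_memory_attractors_merge_unstimulated(self, params):
        _, events = bifurcation_sweep(params, "gamma_IE", np.linspace(0.1, 0.25, 16), stim=None)
        # WM pair and saddle pair annihilate: 5 points collapse to 1
        assert any(e["signature_before"][2] == 5 and e["signature_after"][2] == 1 for e in events)

    def test_baseline_drive_sweep_tau_slow_u_shaped(self, params):
        stim = _stim0(params)
        table, _ = bifurcation_sweep(params, "nu0_I", np.linspace(9.0, 16.0, 29), stim=stim)
        sym = table[(table.stability == "saddle") & (np.abs(table.r1 - table.r2) < 0.1)]
        ts = sym.groupby("value").tau_slow.first().dropna()
        vals = ts.values
        imin = int(np.argmin(vals))
        assert 0 < imin < len(vals) - 1
        assert np.all(np.diff(vals[: imin + 1]) < 0)
        assert np.all(np.diff(vals[imin:]) > 0)
        # the two regime baselines straddle the minimum
        assert 11.5 < ts.index[imin] < 14.0
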