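"""Four-variable mean-field model with explicit choice-selective inhibition.

The steady-state (adiabatic) treatment of GABA synapses in the two-variable
reduction is relaxed: the gating variables of the two selective inhibitory
populations become dynamical,

    dS_i/dt = -S_i / tau_NMDA + (1 - S_i) * gamma_kinetic * Phi_E(x_i)   (E pops, i = 1, 2)
    dS_i/dt = -S_i / tau_GABA + Phi_I(x_i)                               (I pops, i = 3, 4)

with inputs x = A S + I_0 + I_stim + I_nu and a 4x4 adjacency A built from
the same/opposite weights of all four connection classes (adding gamma_II
for inhibitory-inhibitory specificity).  Synaptic strengths and background
currents are fixed constants calibrated (by the upstream inference
procedure) so the excitatory rates match the two-variable model on a
noiseless low-coherence trial; they are data here, not re-derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .meanfield import transfer_rate, _transfer_deriv, noise_step_scale
from .params import TrialSchedule, specificity_to_weights

__all__ = ["FourVarSpecificity", "FourVarParams", "Trajectory4", "build_fourvar", "simulate_fourvar", "find_fixed_points_4", "classify_fourvar"]

# calibrated synaptic constants (nA) and background currents (nA)
J_NMDA_E = 0.4235
J_NMDA_I = 0.5743
J_GABA_E = -0.4699
J_GABA_I = -0.6421
I0_E = 0.7707
I0_I = 1.0267

GAIN_E = (310.0, 125.0, 0.16)
GAIN_I = (615.0, 177.0, 0.087)


@dataclass(frozen=True)
class FourVarSpecificity:
    gamma_EE: float = 0.32
    gamma_EI: float = 0.25
    gamma_IE: float = 0.0
    gamma_II: float = 0.0

    def __post_init__(self) -> None:
        for name in ("gamma_EE", "gamma_EI"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("gamma_IE", "gamma_II"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [-1, 1]")


@dataclass(frozen=True)
class FourVarParams:
    specificity: FourVarSpecificity = field(default_factory=FourVarSpecificity)
    J_NMDA_E: float = J_NMDA_E
    J_NMDA_I: float = J_NMDA_I
    J_GABA_E: float = J_GABA_E
    J_GABA_I: float = J_GABA_I
    I0_E: float = I0_E
    I0_I: float = I0_I
    gain_E: tuple = GAIN_E
    gain_I: tuple = GAIN_I
    tau_NMDA: float = 0.1
    tau_GABA: float = 0.005
    gamma_kinetic: float = 0.641
    J_AMPA_ext: float = 5.2e-4
    mu: float = 40.0
    noise_sd: float = 0.2
    tau_AMPA: float = 0.002
    dt: float = 0.002
    noise_convention: str = "white_amplitude"
    schedule: TrialSchedule = field(default_factory=TrialSchedule)
    S_init_E: float = 0.1
    S_init_I: float = 0.05
    # 'coherence': stimulus strength 0.05 means c = 0.05 in the Eq-4 form;
    # 'current': a direct current of that many nA to population 1
    stimulus_convention: str = "coherence"

    def __post_init__(self) -> None:
        if self.J_NMDA_E <= 0 or self.J_NMDA_I <= 0:
            raise ValueError("NMDA synaptic strengths must be positive")
        if self.J_GABA_E >= 0 or self.J_GABA_I >= 0:
            raise ValueError("GABA synaptic strengths must be negative")


@dataclass
class Trajectory4:
    times: np.ndarray
    S_E1: np.ndarray
    S_E2: np.ndarray
    S_I1: np.ndarray
    S_I2: np.ndarray
    r_E1: np.ndarray
    r_E2: np.ndarray
    r_I1: np.ndarray
    r_I2: np.ndarray
    seed: int
    i_on: int
    i_off: int
    dt: float


def build_fourvar(spec: FourVarSpecificity | None = None, **kwargs) -> tuple[FourVarParams, np.ndarray]:
    """Assemble parameters and the 4x4 adjacency matrix.

    Rows/columns order (E1, E2, I1, I2).  Excitatory columns carry
    J_NMDA,* (> 0), inhibitory columns J_GABA,* (< 0); same-preference
    entries use w+, opposite-preference w-.
    """
    params = FourVarParams(specificity=spec or FourVarSpecificity(), **kwargs)
    s = params.specificity
    wEEp, wEEm = specificity_to_weights(s.gamma_EE)
    wEIp, wEIm = specificity_to_weights(s.gamma_EI)
    wIEp, wIEm = specificity_to_weights(s.gamma_IE)
    wIIp, wIIm = specificity_to_weights(s.gamma_II)
    jne, jni, jge, jgi = params.J_NMDA_E, params.J_NMDA_I, params.J_GABA_E, params.J_GABA_I
    A = np.array(
        [
            [wEEp * jne, wEEm * jne, wIEp * jge, wIEm * jge],
            [wEEm * jne, wEEp * jne, wIEm * jge, wIEp * jge],
            [wEIp * jni, wEIm * jni, wIIp * jgi, wIIm * jgi],
            [wEIm * jni, wEIp * jni, wIIm * jgi, wIIp * jgi],
        ]
    )
    return params, A


def _stim_currents(params: FourVarParams, strength: float) -> tuple[float, float]:
    if params.stimulus_convention == "current":
        return strength, strength
    base = params.J_AMPA_ext * params.mu
    return base * (1.0 - strength / 100.0), base * (1.0 + strength / 100.0)


def _drift(S: np.ndarray, A: np.ndarray, params: FourVarParams, Ist1: float = 0.0, Ist2: float = 0.0, I_eta: np.ndarray | None = None):
    """Vector field for state S with shape (..., 4)."""
    I0 = np.array([params.I0_E, params.I0_E, params.I0_I, params.I0_I])
    Ist = np.array([Ist1, Ist2, 0.0, 0.0])
    x = S @ A.T + I0 + Ist
    if I_eta is not None:
        x = x + I_eta
    rE = transfer_rate(x[..., :2], params.gain_E)
    rI = transfer_rate(x[..., 2:], params.gain_I)
    dS = np.empty_like(S)
    dS[..., :2] = -S[..., :2] / params.tau_NMDA + (1.0 - S[..., :2]) * params.gamma_kinetic * rE
    dS[..., 2:] = -S[..., 2:] / params.tau_GABA + rI
    return dS, rE, rI


def simulate_fourvar(params: FourVarParams, A: np.ndarray, stim_strength: float, seed: int, noise_sd: float | None = None) -> Trajectory4:
    """Euler integration of one trial; noise enters all four populations."""
    p = params
    sched = p.schedule
    n_steps = int(round(sched.total / p.dt))
    i_on = int(round(sched.pre / p.dt))
    i_off = int(round((sched.pre + sched.stim) / p.dt))
    Ist1, Ist2 = _stim_currents(p, stim_strength)
    rng = np.random.default_rng(seed)
    sd = p.noise_sd if noise_sd is None else noise_sd
    decay = 1.0 - p.dt / p.tau_AMPA
    scale = noise_step_scale(p.dt, sd, p.tau_AMPA, p.noise_convention)

    S = np.array([p.S_init_E, p.S_init_E, p.S_init_I, p.S_init_I])
    # equilibrate the fast GABA gating at the initial excitatory state so
    # trials start without an inhibitory transient (damped relaxation: the
    # undamped map is unstable because of the I->I feedback)
    I0v = np.array([p.I0_E, p.I0_E, p.I0_I, p.I0_I])
    for _ in range(400):
        x = S @ A.T + I0v
        target = p.tau_GABA * transfer_rate(x[2:], p.gain_I)
        S[2:] += 0.1 * (target - S[2:])
    I_eta = np.zeros(4)
    rec = {k: np.empty(n_steps) for k in ("S_E1", "S_E2", "S_I1", "S_I2", "r_E1", "r_E2", "r_I1", "r_I2")}
    for t in range(n_steps):
        on = i_on <= t < i_off
        dS, rE, rI = _drift(S, A, p, Ist1 if on else 0.0, Ist2 if on else 0.0, I_eta)
        rec["S_E1"][t], rec["S_E2"][t], rec["S_I1"][t], rec["S_I2"][t] = S
        rec["r_E1"][t], rec["r_E2"][t] = rE
        rec["r_I1"][t], rec["r_I2"][t] = rI
        S = S + p.dt * dS
        if np.any(S[:2] < -1e-6) or np.any(S[:2] > 1 + 1e-6):
            raise FloatingPointError("excitatory gating left [0, 1]")
        S[:2] = np.clip(S[:2], 0.0, 1.0)
        S[2:] = np.maximum(S[2:], 0.0)
        I_eta = I_eta * decay + scale * rng.standard_normal(4)
    return Trajectory4(
        times=np.arange(n_steps) * p.dt,
        **rec,
        seed=seed,
        i_on=i_on,
        i_off=i_off,
        dt=p.dt,
    )


def find_fixed_points_4(
    params: FourVarParams,
    A: np.ndarray,
    stim_strength: float | None = None,
    n_grid_E: int = 9,
    n_levels_I: int = 5,
    tol: float = 1e-6,
) -> list[dict]:
    """Multistart damped-Newton root finding in (S_E1, S_E2, S_I1, S_I2).

    S_I is bounded by tau_GABA times the maximum attainable inhibitory rate;
    stability is classified from the eigenvalues of the 4x4 analytic
    Jacobian.  Labels follow the projection onto the excitatory plane.
    """
    p = params
    Ist1, Ist2 = (0.0, 0.0) if stim_strength is None else _stim_currents(p, stim_strength)
    I0 = np.array([p.I0_E, p.I0_E, p.I0_I, p.I0_I])
    Ist = np.array([Ist1, Ist2, 0.0, 0.0])

    gE = np.linspace(0, 1, n_grid_E)
    # physical range of the GABA gating at operating inhibitory rates
    SI_max = 1.5
    gI = np.linspace(0, SI_max * 0.9, n_levels_I)
    starts = np.array(np.meshgrid(gE, gE, gI, gI, indexing="ij")).reshape(4, -1).T

    def jac_batch(S):
        # S: (B, 4) -> (B, 4, 4) analytic Jacobians
        x = S @ A.T + I0 + Ist
        dE = _transfer_deriv(x[:, :2], p.gain_E)
        dI = _transfer_deriv(x[:, 2:], p.gain_I)
        rE = transfer_rate(x[:, :2], p.gain_E)
        B = S.shape[0]
        J = np.zeros((B, 4, 4))
        for i in range(2):
            J[:, i, :] = ((1.0 - S[:, i]) * p.gamma_kinetic * dE[:, i])[:, None] * A[i]
            J[:, i, i] += -1.0 / p.tau_NMDA - p.gamma_kinetic * rE[:, i]
        for i in range(2, 4):
            J[:, i, :] = dI[:, i - 2][:, None] * A[i]
            J[:, i, i] += -1.0 / p.tau_GABA
        return J

    S = starts.copy()
    lam = 1e-9
    eye = np.eye(4)
    for _ in range(120):
        F, _, _ = _drift(S, A, p, Ist1, Ist2)
        J = jac_batch(S)
        JtJ = np.einsum("bij,bik->bjk", J, J) + lam * eye
        JtF = np.einsum("bij,bi->bj", J, F)
        try:
            step = -np.linalg.solve(JtJ, JtF[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = -np.einsum("bij,bi->bj", np.linalg.pinv(JtJ.transpose(0, 2, 1)), JtF)
        nrm = np.linalg.norm(step, axis=1, keepdims=True)
        step = step * np.minimum(1.0, 0.25 / np.maximum(nrm, 1e-300))
        S = S + step
        S[:, :2] = np.clip(S[:, :2], -0.05, 1.05)
        S[:, 2:] = np.clip(S[:, 2:], -0.05, SI_max)
    F, _, _ = _drift(S, A, p, Ist1, Ist2)
    ok = (
        (np.max(np.abs(F), axis=1) <= tol)
        & np.all(S[:, :2] > -1e-6, axis=1)
        & np.all(S[:, :2] < 1 + 1e-6, axis=1)
        & np.all(S[:, 2:] > -1e-6, axis=1)
    )
    roots: list[np.ndarray] = []
    for cand in S[ok]:
        cand = np.concatenate([np.clip(cand[:2], 0, 1), np.maximum(cand[2:], 0)])
        if not any(np.linalg.norm(cand - r) < 1e-4 for r in roots):
            roots.append(cand)

    def jac(Sv):
        return jac_batch(Sv[None, :])[0]

    out = []
    for S in roots:
        ev = np.linalg.eigvals(jac(S))
        reals = np.sort(ev.real)[::-1]
        if reals[0] < 0:
            stability = "attractor"
        elif reals[0] > 0 and (ev.real > 0).sum() == 1:
            stability = "saddle"
        else:
            stability = "repeller"
        x = S @ A.T + I0 + Ist
        rE = transfer_rate(x[:2], p.gain_E)
        out.append(
            {
                "S": S,
                "rates_E": (float(rE[0]), float(rE[1])),
                "stability": stability,
                "eigenvalues": ev,
                "tau_slow": float(1.0 / reals[0]) if stability == "saddle" else None,
            }
        )
    out.sort(key=lambda r: (r["S"][0] + r["S"][1], r["S"][0] - r["S"][1]))
    return out


def classify_fourvar(params: FourVarParams, A: np.ndarray, rate_threshold: float = 15.0, symmetry_tol: float = 0.1) -> dict:
    """Census of both planes projected onto (S_E1, S_E2)."""
    unstim = find_fixed_points_4(params, A)
    stim = find_fixed_points_4(params, A, stim_strength=0.0)

    def counts(fps):
        return (
            sum(f["stability"] == "attractor" for f in fps),
            sum(f["stability"] == "saddle" for f in fps),
            len(fps),
        )

    def has_low_state(fps):
        return any(
            f["stability"] == "attractor"
            and abs(f["rates_E"][0] - f["rates_E"][1]) < symmetry_tol
            and max(f["rates_E"]) < rate_threshold
            for f in fps
        )

    cu, cs = counts(unstim), counts(stim)
    good = cu[:2] == (3, 2) and cs[:2] == (2, 1)
    return {
        "unstim": unstim,
        "stim": stim,
        "n_unstim": cu,
        "n_stim": cs,
        "low_state_attractor": has_low_state(unstim),
        "is_good_decision_circuit": bool(good and has_low_state(unstim)),
    }
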