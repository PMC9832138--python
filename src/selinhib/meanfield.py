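"""Stochastic simulation of the two-variable mean-field decision circuit.

State variables are the NMDA gating fractions ``S1, S2`` of the two
choice-selective excitatory populations,

    dS_i/dt = -S_i / tau_NMDA + (1 - S_i) * gamma_kinetic * Phi(x_i),

with the current-to-rate transfer ``Phi(x) = (a x - b) / (1 - exp(-d (a x - b)))``
and input currents assembled from the effective couplings, the external
stimulus, and an AMPA-filtered noise current.  Integration is forward Euler
at ``dt`` = 2 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .couplings import DerivedCouplings, derive_couplings
from .params import CircuitParams, TrialSchedule

__all__ = [
    "StimulusSpec",
    "Trajectory",
    "transfer_rate",
    "stimulus_current",
    "step_noise",
    "noise_step_scale",
    "stationary_noise_sd",
    "inhibitory_rates",
    "simulate_trial",
    "simulate_trials",
]


@dataclass(frozen=True)
class StimulusSpec:
    """External stimulus: rate increase ``mu`` (Hz) split by coherence.

    Positive coherence favors population 2: during [t_on, t_off) population 1
    receives ``J_AMPA_ext * mu * (1 - c/100)`` and population 2
    ``J_AMPA_ext * mu * (1 + c/100)``; both are zero outside the window.
    """

    mu: float = 40.0
    coherence_c: float = 0.0
    t_on: float = 0.5
    t_off: float = 1.5

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if not -100.0 <= self.coherence_c <= 100.0:
            raise ValueError("coherence must be in [-100, 100] percent")
        if not self.t_on < self.t_off:
            raise ValueError("stimulus window must satisfy t_on < t_off")

    @classmethod
    def from_schedule(cls, schedule: TrialSchedule, coherence_c: float, mu: float = 40.0) -> "StimulusSpec":
        return cls(mu=mu, coherence_c=coherence_c, t_on=schedule.pre, t_off=schedule.pre + schedule.stim)


@dataclass
class Trajectory:
    """Recorded trial: times, gating variables, rates, and noise currents."""

    times: np.ndarray
    S1: np.ndarray
    S2: np.ndarray
    r_E1: np.ndarray
    r_E2: np.ndarray
    r_I1: np.ndarray
    r_I2: np.ndarray
    I_eta1: np.ndarray
    I_eta2: np.ndarray
    seed: int
    stimulus: StimulusSpec
    schedule: TrialSchedule
    dt: float
    clipped: bool = False
    i_on: int = 0
    i_off: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.times,
                "S1": self.S1,
                "S2": self.S2,
                "rE1": self.r_E1,
                "rE2": self.r_E2,
                "rI1": self.r_I1,
                "rI2": self.r_I2,
                "Ieta1": self.I_eta1,
                "Ieta2": self.I_eta2,
            }
        )


def transfer_rate(x, gain=(270.0, 108.0, 0.154)):
    """Current-to-rate transfer Phi(x) = (a x - b) / (1 - exp(-d (a x - b))).

    Continuous at the removable singularity a*x = b (limit 1/d) and
    non-negative for all finite inputs.
    """
    a, b, d = gain
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("transfer_rate requires finite input current")
    z = a * x - b
    small = np.abs(z) < 1e-10
    zc = np.clip(z, -500.0 / d, 500.0 / d)
    denom = 1.0 - np.exp(-d * zc)
    out = np.where(small, 1.0 / d, zc / np.where(small, 1.0, denom))
    return out if out.ndim else float(out)


def _transfer_deriv(x, gain=(270.0, 108.0, 0.154)):
    """Analytic dPhi/dx; at the removable singularity the limit is a/2."""
    a, b, d = gain
    x = np.asarray(x, dtype=float)
    z = a * x - b
    small = np.abs(z) < 1e-6
    zc = np.clip(z, -500.0 / d, 500.0 / d)
    e = np.exp(-d * zc)
    denom = (1.0 - e) ** 2
    out = np.where(small, a / 2.0, a * (1.0 - e - d * zc * e) / np.where(small, 1.0, denom))
    return out if out.ndim else float(out)


def stimulus_current(t: float, stim: StimulusSpec, J_AMPA_ext: float = 5.2e-4) -> tuple[float, float]:
    """Stimulus currents (I1, I2) in nA at time t."""
    if stim.t_on <= t < stim.t_off:
        base = J_AMPA_ext * stim.mu
        return base * (1.0 - stim.coherence_c / 100.0), base * (1.0 + stim.coherence_c / 100.0)
    return 0.0, 0.0


def noise_step_scale(dt: float, noise_sd: float, tau_AMPA: float, convention: str = "white_amplitude") -> float:
    """Per-step Gaussian amplitude of the Euler-Maruyama OU update.

    The update is ``I <- I * (1 - dt/tau) + scale * N(0, 1)``.  Under the
    'white_amplitude' convention ``scale = sqrt(dt) * noise_sd / sqrt(tau)``;
    under 'stationary_sd' the amplitude is rescaled so the stationary
    standard deviation of I equals ``noise_sd`` exactly.
    """
    decay = 1.0 - dt / tau_AMPA
    scale = math.sqrt(dt) * noise_sd / math.sqrt(tau_AMPA)
    if convention == "stationary_sd":
        stat = scale / math.sqrt(1.0 - decay**2) if abs(decay) < 1 else scale
        scale *= noise_sd / stat
    return scale


def stationary_noise_sd(dt: float, noise_sd: float, tau_AMPA: float, convention: str = "white_amplitude") -> float:
    """Closed-form stationary sd of the discretized OU noise current."""
    decay = 1.0 - dt / tau_AMPA
    scale = noise_step_scale(dt, noise_sd, tau_AMPA, convention)
    return scale / math.sqrt(1.0 - decay**2)


def step_noise(I_eta: float, dt: float, noise_sd: float, tau_AMPA: float, rng: np.random.Generator, convention: str = "white_amplitude") -> float:
    """One Euler-Maruyama update of the AMPA-filtered noise current."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    decay = 1.0 - dt / tau_AMPA
    scale = noise_step_scale(dt, noise_sd, tau_AMPA, convention)
    return I_eta * decay + scale * rng.standard_normal()


def inhibitory_rates(S1, S2, couplings: DerivedCouplings, floor: bool = True):
    """Linearized firing rates of the two selective inhibitory populations.

    Affine in (S1, S2); the same-preference coefficient exceeds the
    opposite-preference one when gamma_EI > 0, which is how inhibitory
    populations inherit choice selectivity.  Reported rates are floored at
    zero; the affine form itself (not the floored value) is what the
    reduction uses internally.
    """
    S1 = np.asarray(S1, dtype=float)
    S2 = np.asarray(S2, dtype=float)
    if np.any((S1 < -1e-9) | (S1 > 1 + 1e-9)) or np.any((S2 < -1e-9) | (S2 > 1 + 1e-9)):
        raise ValueError("gating variables must lie in [0, 1]")
    r1 = couplings.alpha1_I * S1 + couplings.alpha2_I * S2 + couplings.I0_II
    r2 = couplings.alpha1_I * S2 + couplings.alpha2_I * S1 + couplings.I0_II
    if floor:
        r1 = np.maximum(r1, 0.0)
        r2 = np.maximum(r2, 0.0)
    return r1, r2


def drift(S1, S2, params: CircuitParams, couplings: DerivedCouplings, I_ext1=0.0, I_ext2=0.0):
    """Noiseless vector field (dS1/dt, dS2/dt)."""
    x1 = couplings.alpha1 * S1 + couplings.alpha2 * S2 + couplings.I0_1 + I_ext1
    x2 = couplings.alpha1 * S2 + couplings.alpha2 * S1 + couplings.I0_2 + I_ext2
    r1 = transfer_rate(x1, params.gain)
    r2 = transfer_rate(x2, params.gain)
    g = params.gamma_kinetic
    return (
        -S1 / params.tau_NMDA + (1.0 - S1) * g * r1,
        -S2 / params.tau_NMDA + (1.0 - S2) * g * r2,
    )


def simulate_trials(
    params: CircuitParams,
    stim: StimulusSpec,
    n_trials: int,
    seed: int,
    couplings: DerivedCouplings | None = None,
    nu0_I_stim: float | None = None,
    noise_sd: float | None = None,
    record: bool = True,
):
    """Vectorized integration of ``n_trials`` independent trials.

    Population-1 and population-2 noise increments are drawn interleaved from
    a single per-call generator (one (2, n) standard-normal block per step),
    so a single-trial run reproduces trial i of a batched run only when
    seeded identically with the same n.  ``nu0_I_stim`` applies a modified
    baseline inhibitory drive during the stimulus window only (perturbation
    experiments).

    Returns a dict of arrays with keys ``S1, S2, rE1, rE2, rI1, rI2,
    Ieta1, Ieta2`` (each (n_trials, n_steps)) plus window indices.
    """
    p = params
    c = couplings if couplings is not None else derive_couplings(p)
    sched = p.schedule
    n_steps = int(round(sched.total / p.dt))
    i_on = int(round(stim.t_on / p.dt))
    i_off = int(round(stim.t_off / p.dt))
    rng = np.random.default_rng(seed)

    sd = p.noise_sd if noise_sd is None else noise_sd
    decay = 1.0 - p.dt / p.tau_AMPA
    scale = noise_step_scale(p.dt, sd, p.tau_AMPA, p.noise_convention)

    I0_base = c.I0_1
    if nu0_I_stim is not None:
        from .couplings import background_current

        I0_stim_epoch = background_current(p, nu0_I_stim)
    else:
        I0_stim_epoch = I0_base

    Ist1 = stim.mu * p.J_AMPA_ext * (1.0 - stim.coherence_c / 100.0)
    Ist2 = stim.mu * p.J_AMPA_ext * (1.0 + stim.coherence_c / 100.0)

    S1 = np.full(n_trials, p.S_init)
    S2 = np.full(n_trials, p.S_init)
    I1 = np.zeros(n_trials)
    I2 = np.zeros(n_trials)

    out = None
    if record:
        out = {k: np.empty((n_trials, n_steps)) for k in ("S1", "S2", "rE1", "rE2", "rI1", "rI2", "Ieta1", "Ieta2")}

    g = p.gamma_kinetic
    a1, a2 = c.alpha1, c.alpha2
    clipped = False
    for t in range(n_steps):
        on = i_on <= t < i_off
        I0t = I0_stim_epoch if on else I0_base
        b1 = a1 * S1 + a2 * S2 + I0t + (Ist1 if on else 0.0)
        b2 = a1 * S2 + a2 * S1 + I0t + (Ist2 if on else 0.0)
        r1 = transfer_rate(b1 + I1, p.gain)
        r2 = transfer_rate(b2 + I2, p.gain)
        if record:
            if p.rates_include_noise:
                rr1, rr2 = r1, r2
            else:
                rr1 = transfer_rate(b1, p.gain)
                rr2 = transfer_rate(b2, p.gain)
            rI1, rI2 = inhibitory_rates(np.clip(S1, 0, 1), np.clip(S2, 0, 1), c)
            out["S1"][:, t] = S1
            out["S2"][:, t] = S2
            out["rE1"][:, t] = rr1
            out["rE2"][:, t] = rr2
            out["rI1"][:, t] = rI1
            out["rI2"][:, t] = rI2
            out["Ieta1"][:, t] = I1
            out["Ieta2"][:, t] = I2
        S1 = S1 + p.dt * (-S1 / p.tau_NMDA + (1.0 - S1) * g * r1)
        S2 = S2 + p.dt * (-S2 / p.tau_NMDA + (1.0 - S2) * g * r2)
        eps = 1e-6
        if np.any(S1 < -eps) or np.any(S1 > 1 + eps) or np.any(S2 < -eps) or np.any(S2 > 1 + eps):
            raise FloatingPointError("gating variable left [0, 1]: integration unstable")
        if np.any(S1 < 0) or np.any(S1 > 1) or np.any(S2 < 0) or np.any(S2 > 1):
            clipped = True
            S1 = np.clip(S1, 0.0, 1.0)
            S2 = np.clip(S2, 0.0, 1.0)
        z = rng.standard_normal((2, n_trials))
        I1 = I1 * decay + scale * z[0]
        I2 = I2 * decay + scale * z[1]

    result = {
        "i_on": i_on,
        "i_off": i_off,
        "n_steps": n_steps,
        "clipped": clipped,
        "times": np.arange(n_steps) * p.dt,
    }
    if record:
        result.update(out)
    return result


def simulate_trial(params: CircuitParams, stim: StimulusSpec, seed: int, couplings: DerivedCouplings | None = None, **kwargs) -> Trajectory:
    """Integrate a single trial and return its full Trajectory."""
    res = simulate_trials(params, stim, 1, seed, couplings=couplings, **kwargs)
    return Trajectory(
        times=res["times"],
        S1=res["S1"][0],
        S2=res["S2"][0],
        r_E1=res["rE1"][0],
        r_E2=res["rE2"][0],
        r_I1=res["rI1"][0],
        r_I2=res["rI2"][0],
        I_eta1=res["Ieta1"][0],
        I_eta2=res["Ieta2"][0],
        seed=seed,
        stimulus=stim,
        schedule=params.schedule,
        dt=params.dt,
        clipped=res["clipped"],
        i_on=res["i_on"],
        i_off=res["i_off"],
    )
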