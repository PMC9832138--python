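"""Behavioral evaluation of simulated decision trials.

A trial is *valid* when (i) the excitatory rate difference stays below
5 Hz throughout the pre-stimulus epoch and (ii) it exceeds the 15 Hz
decision threshold at some step within the stimulus window or at the first
step after offset.  The choice is the population leading at the first
qualifying crossing; decision time is that crossing time relative to
stimulus onset (one-step resolution, no interpolation).  Invalid trials are
reported as their own outcome category and are never assigned a random
choice; psychometric and chronometric summaries use valid trials only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .couplings import derive_couplings
from .meanfield import StimulusSpec, simulate_trials
from .params import CircuitParams

__all__ = [
    "TrialOutcome",
    "BehaviorSummary",
    "evaluate_trial",
    "evaluate_batch",
    "run_session",
    "working_memory_probability",
    "perturbation_experiment",
]

PRE_THRESHOLD = 5.0  # Hz
DECISION_THRESHOLD = 15.0  # Hz


@dataclass(frozen=True)
class TrialOutcome:
    valid: bool
    invalid_reason: str  # 'premature_separation' | 'no_threshold_crossing' | 'none'
    choice: int  # 1, 2, or 0 for none
    decision_time: float | None  # s from stimulus onset
    maintained_after_delay: bool | None = None


@dataclass
class BehaviorSummary:
    """Per-coherence aggregates over a session of simulated trials."""

    table: pd.DataFrame
    trials: pd.DataFrame
    pre_threshold: float = PRE_THRESHOLD
    decision_threshold: float = DECISION_THRESHOLD
    seed: int | None = None
    coherences: tuple = field(default_factory=tuple)


def _evaluate_arrays(
    dR: np.ndarray,
    i_on: int,
    i_off: int,
    dt: float,
    pre_threshold: float = PRE_THRESHOLD,
    decision_threshold: float = DECISION_THRESHOLD,
    strict_window: bool = False,
):
    """Vectorized outcome evaluation on rate-difference arrays (n, T).

    The crossing window is [t_on, t_off] union the first post-offset step;
    ``strict_window=True`` additionally requires the separation to persist
    at the step following offset (the stricter reading of the criterion).
    """
    n, T = dR.shape
    last = min(i_off + 1, T)
    pre_ok = (np.abs(dR[:, :i_on]) < pre_threshold).all(axis=1) if i_on > 0 else np.ones(n, bool)
    window = np.abs(dR[:, i_on:last]) >= decision_threshold
    crossed = window.any(axis=1)
    if strict_window and last > i_off:
        crossed &= np.abs(dR[:, i_off]) >= decision_threshold
    valid = pre_ok & crossed
    first = np.where(crossed, window.argmax(axis=1), 0)
    decision_time = first * dt
    lead = dR[np.arange(n), i_on + first]
    choice = np.where(valid, np.where(lead > 0, 1, 2), 0)
    reason = np.where(valid, "none", np.where(~pre_ok, "premature_separation", "no_threshold_crossing"))
    return valid, choice, decision_time, reason


def evaluate_trial(
    traj,
    pre_threshold: float = PRE_THRESHOLD,
    decision_threshold: float = DECISION_THRESHOLD,
    strict_window: bool = False,
) -> TrialOutcome:
    """Classify a single Trajectory into a TrialOutcome."""
    if traj.i_off <= traj.i_on or traj.i_on < 0:
        raise ValueError("trajectory must cover pre-stimulus and stimulus epochs")
    if len(traj.r_E1) <= traj.i_off:
        raise ValueError("trajectory missing post-stimulus step")
    dR = (np.asarray(traj.r_E1) - np.asarray(traj.r_E2))[None, :]
    valid, choice, t_dec, reason = _evaluate_arrays(
        dR, traj.i_on, traj.i_off, traj.dt, pre_threshold, decision_threshold, strict_window
    )
    return TrialOutcome(
        valid=bool(valid[0]),
        invalid_reason=str(reason[0]),
        choice=int(choice[0]),
        decision_time=float(t_dec[0]) if valid[0] else None,
    )


def evaluate_batch(res: dict, dt: float, **kwargs):
    """Outcome arrays for a batched simulate_trials result."""
    dR = res["rE1"] - res["rE2"]
    return _evaluate_arrays(dR, res["i_on"], res["i_off"], dt, **kwargs)


def _correct_choice(coherence: float) -> int:
    # positive coherence drives population 2 (it receives the larger input)
    return 2 if coherence > 0 else 1


def run_session(
    params: CircuitParams,
    coherences,
    n_per_coherence: int,
    seed: int,
    nu0_I_stim: float | None = None,
    record_delay: bool = True,
) -> BehaviorSummary:
    """Simulate a behavioral session and aggregate per coherence.

    Per-coherence batches use child seeds spawned deterministically from the
    session seed, so adding coherences never perturbs existing conditions.
    Accuracy and decision times are computed over valid trials only;
    completion is the valid fraction of all trials.
    """
    couplings = derive_couplings(params)
    rows = []
    trial_rows = []
    for k, c in enumerate(coherences):
        child_seed = int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))
        stim = StimulusSpec.from_schedule(params.schedule, coherence_c=c)
        res = simulate_trials(params, stim, n_per_coherence, child_seed, couplings=couplings, nu0_I_stim=nu0_I_stim)
        valid, choice, t_dec, reason = evaluate_batch(res, params.dt)
        if record_delay and res["n_steps"] > res["i_off"]:
            dR_end = np.abs(res["rE1"][:, -1] - res["rE2"][:, -1])
            maintained = valid & (dR_end >= DECISION_THRESHOLD)
        else:
            maintained = np.zeros_like(valid)
        correct = _correct_choice(c)
        acc = float((choice[valid] == correct).mean()) if valid.any() and c != 0 else np.nan
        t_valid = t_dec[valid]
        rows.append(
            {
                "coherence": c,
                "n_trials": n_per_coherence,
                "completion": float(valid.mean()),
                "premature_fraction": float((reason == "premature_separation").mean()),
                "accuracy": acc,
                "p_choice2": float((choice[valid] == 2).mean()) if valid.any() else np.nan,
                "mean_decision_time": float(t_valid.mean()) if valid.any() else np.nan,
                "sem_decision_time": float(t_valid.std(ddof=1) / np.sqrt(len(t_valid))) if valid.sum() > 1 else np.nan,
                "p_maintained": float(maintained[valid].mean()) if valid.any() else np.nan,
                "seed": child_seed,
            }
        )
        for i in range(n_per_coherence):
            trial_rows.append(
                {
                    "coherence": c,
                    "trial": i,
                    "valid": bool(valid[i]),
                    "reason": reason[i],
                    "choice": int(choice[i]),
                    "decision_time": float(t_dec[i]) if valid[i] else np.nan,
                    "maintained": bool(maintained[i]),
                }
            )
    return BehaviorSummary(
        table=pd.DataFrame(rows),
        trials=pd.DataFrame(trial_rows),
        seed=seed,
        coherences=tuple(coherences),
    )


def working_memory_probability(
    params: CircuitParams,
    delay: float | None = None,
    n: int = 200,
    seed: int = 0,
    coherence: float = 0.0,
) -> float | None:
    """P(separation still >= 15 Hz at the end of the post-offset delay).

    Conditioned on trials with a valid decision; returns None when no trial
    is valid.  ``delay`` overrides the schedule's post-stimulus epoch.
    """
    p = params
    if delay is not None:
        p = p.replace(schedule=p.schedule.__class__(pre=p.schedule.pre, stim=p.schedule.stim, post=delay))
    stim = StimulusSpec.from_schedule(p.schedule, coherence_c=coherence)
    res = simulate_trials(p, stim, n, seed, couplings=derive_couplings(p))
    valid, choice, t_dec, reason = evaluate_batch(res, p.dt)
    if not valid.any():
        return None
    dR_end = np.abs(res["rE1"][:, -1] - res["rE2"][:, -1])
    return float((dR_end[valid] >= DECISION_THRESHOLD).mean())


def perturbation_experiment(
    params: CircuitParams,
    baseline_nu0_I: float | None = None,
    deltas=(-0.5, -0.25, 0.0, 0.25, 0.5),
    coherences=(0.0, 5.0, 10.0),
    completion_coherences=None,
    n: int = 500,
    seed: int = 0,
    common_random_numbers: bool = True,
) -> pd.DataFrame:
    """Modulate the baseline inhibitory drive during the stimulus epoch.

    For each delta in ``deltas`` (Hz, within [-0.5, 0.5]), simulates sessions
    with the perturbed drive applied only inside the stimulus window and
    reports changes in completion, accuracy, and mean decision time relative
    to delta = 0.  With common random numbers (default) the same per-trial
    noise is used at every delta, so the delta = 0 row is exactly zero.
    """
    base = params.nu0_I if baseline_nu0_I is None else baseline_nu0_I
    p = params.replace(nu0_I=base)
    comp_cs = coherences if completion_coherences is None else completion_coherences
    all_cs = sorted(set(tuple(coherences) + tuple(comp_cs)))

    def session(delta: float, s: int):
        return run_session(p, all_cs, n, seed=s, nu0_I_stim=base + delta)

    rows = []
    ref = None
    for j, d in enumerate(deltas):
        s = seed if common_random_numbers else seed + 1000 * j
        summ = session(d, s).table.set_index("coherence")
        comp = float(summ.loc[list(comp_cs), "completion"].mean())
        acc = float(summ.loc[[c for c in coherences if c != 0], "accuracy"].mean())
        dt_ = float(summ.loc[list(coherences), "mean_decision_time"].mean())
        if d == 0.0:
            ref = (comp, acc, dt_)
        rows.append({"delta_nu": d, "completion": comp, "accuracy": acc, "mean_decision_time": dt_})
    if ref is None:
        summ = session(0.0, seed).table.set_index("coherence")
        ref = (
            float(summ.loc[list(comp_cs), "completion"].mean()),
            float(summ.loc[[c for c in coherences if c != 0], "accuracy"].mean()),
            float(summ.loc[list(coherences), "mean_decision_time"].mean()),
        )
    out = pd.DataFrame(rows)
    out["d_completion"] = out["completion"] - ref[0]
    out["d_accuracy"] = out["accuracy"] - ref[1]
    out["d_decision_time"] = out["mean_decision_time"] - ref[2]
    return out
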