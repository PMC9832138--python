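"""Shared engineering: seeding, run manifests, fixtures, experiment drivers.

Seed discipline: every experiment takes one master seed; child seeds are
derived with ``numpy.random.SeedSequence([master, counter])`` so that adding
conditions or trials never perturbs the random streams of existing ones.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .params import CircuitParams, params_to_dict

__all__ = [
    "child_seed",
    "RunManifest",
    "make_fixture",
    "run_experiment",
]


def child_seed(master: int, *counters: int) -> int:
    """Deterministic child seed below 2**31 from a master seed and counters."""
    return int(np.random.SeedSequence([int(master), *map(int, counters)]).generate_state(1)[0] % (2**31))


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Reproducibility record for one experiment run."""

    name: str
    master_seed: int
    config: dict
    derived_seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # filename -> sha256 prefix
    started: str = ""
    finished: str = ""
    status: str = "running"

    def register_output(self, path: str | Path) -> None:
        path = Path(path)
        self.outputs[path.name] = _hash_file(path)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def make_fixture(kind: str, seed: int = 0, **spec):
    """Constructed test inputs with exactly known ground truth.

    kinds:
      - ``step_trajectory``: rate traces crossing a given separation at a
        prescribed step (fields: n_steps, i_on, i_off, cross_step,
        separation, dt, pre_separation)
      - ``planted_weight_matrix``: block matrix with planted same/opposite
        means (fields: n_per_group, w_same, w_opposite, noise_sd)
      - ``synthetic_unit_activity``: two-class activity with prescribed
        normal shift (fields: n_per_class, shift)
      - ``output_trace``: RNN-style output pair crossing a threshold at a
        prescribed step (fields: n_steps, t_on, cross_step, level)
    """
    rng = np.random.default_rng(seed)
    if kind == "step_trajectory":
        n = spec.get("n_steps", 1250)
        i_on = spec.get("i_on", 250)
        i_off = spec.get("i_off", 750)
        cross = spec.get("cross_step", None)
        sep = spec.get("separation", 20.0)
        pre_sep = spec.get("pre_separation", 0.0)
        dt = spec.get("dt", 0.002)
        r1 = np.full(n, 2.0)
        r2 = np.full(n, 2.0)
        r1[:i_on] += pre_sep
        if cross is not None:
            if not (0 <= cross <= i_off - i_on):
                raise ValueError("cross_step must fall inside the stimulus window")
            r1[i_on + cross:] += sep
        from .meanfield import Trajectory, StimulusSpec
        from .params import TrialSchedule

        sched = TrialSchedule(pre=i_on * dt, stim=(i_off - i_on) * dt, post=(n - i_off) * dt)
        return Trajectory(
            times=np.arange(n) * dt,
            S1=np.zeros(n),
            S2=np.zeros(n),
            r_E1=r1,
            r_E2=r2,
            r_I1=np.zeros(n),
            r_I2=np.zeros(n),
            I_eta1=np.zeros(n),
            I_eta2=np.zeros(n),
            seed=seed,
            stimulus=StimulusSpec(t_on=i_on * dt, t_off=i_off * dt),
            schedule=sched,
            dt=dt,
            i_on=i_on,
            i_off=i_off,
        )
    if kind == "planted_weight_matrix":
        npg = spec.get("n_per_group", 10)
        ws = spec["w_same"]
        wo = spec["w_opposite"]
        sd = spec.get("noise_sd", 0.0)
        n = 2 * npg
        pref = np.repeat([1, 2], npg)
        W = np.where(pref[:, None] == pref[None, :], ws, wo).astype(float)
        if sd:
            W = np.maximum(W + sd * rng.standard_normal(W.shape), 0.0)
        np.fill_diagonal(W, 0.0)
        return W, pref
    if kind == "synthetic_unit_activity":
        npc = spec.get("n_per_class", 50)
        shift = spec.get("shift", 1.0)
        a = rng.standard_normal(npc)
        b = rng.standard_normal(npc) + shift
        acts = np.concatenate([a, b])
        labels = np.concatenate([np.zeros(npc, bool), np.ones(npc, bool)])
        return acts, labels
    if kind == "output_trace":
        n = spec.get("n_steps", 60)
        t_on = spec.get("t_on", 15)
        cross = spec.get("cross_step", 5)
        level = spec.get("level", 0.5)
        z = np.full((n, 2), 0.2)
        z[t_on + cross:, 0] += level
        return z
    raise ValueError(f"unknown fixture kind {kind!r}")


def run_experiment(name: str, params: CircuitParams | None = None, seed: int = 0, out_dir: str | Path | None = None, **options) -> dict:
    """Figure-level experiment drivers chaining the module pipelines.

    names: ``fig2_scan`` (specificity-space classification + correlation),
    ``fig3_behavior`` (psychometric/chronometric/completion for the three
    motifs), ``fig4_wm`` (working-memory probability vs motif),
    ``fig6_perturb`` (perturbation sign table at both baselines),
    ``fig5_rnn`` (train networks, selectivity + specificity estimates).
    Writes CSV tables and a manifest when ``out_dir`` is given.
    """
    from . import analysis, behavior, rnn

    params = params or CircuitParams()
    manifest = RunManifest(name=name, master_seed=seed, config=params_to_dict(params), started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    out: dict = {"name": name}
    try:
        if name == "fig2_scan":
            gEE = options.get("gamma_EE_grid", np.linspace(0.2, 0.5, 15))
            gEI = options.get("gamma_EI_grid", np.linspace(0.0, 1.0, 9))
            gIE = options.get("gamma_IE_grid", np.linspace(-1.0, 1.0, 17))
            table = analysis.scan_specificity(params, gEE, gEI, gIE)
            good = table[table.is_good_decision_circuit]
            corr = float(np.corrcoef(good.gamma_EE, good.specificity_index)[0, 1]) if len(good) > 2 else np.nan
            out.update(table=table, correlation=corr, n_good=int(len(good)))
        elif name == "fig3_behavior":
            coherences = options.get("coherences", (0.0, 5.0, 10.0, 20.0, 50.0))
            n = options.get("n_per_coherence", 200)
            tables = {}
            for i, (label, gIE) in enumerate([("contra", -0.2), ("non", 0.0), ("ipsi", 0.35)]):
                p_i = params.with_specificity(gamma_IE=gIE)
                tables[label] = behavior.run_session(p_i, coherences, n, seed=child_seed(seed, i)).table
            out.update(tables=tables)
        elif name == "fig4_wm":
            delay = options.get("delay", 1.0)
            n = options.get("n", 200)
            rows = []
            for i, gIE in enumerate(options.get("gamma_IE_values", (-0.2, 0.0, 0.2, 0.35))):
                p_i = params.with_specificity(gamma_IE=gIE)
                prob = behavior.working_memory_probability(p_i, delay=delay, n=n, seed=child_seed(seed, i))
                rows.append({"gamma_IE": gIE, "p_maintained": prob})
            out.update(table=pd.DataFrame(rows))
        elif name == "fig6_perturb":
            n = options.get("n", 500)
            tables = {}
            for i, base in enumerate(options.get("baselines", (11.5, 14.0))):
                tables[base] = behavior.perturbation_experiment(params, baseline_nu0_I=base, n=n, seed=child_seed(seed, i))
            out.update(tables=tables)
        elif name == "fig5_rnn":
            n_nets = options.get("n_networks", 3)
            rparams = options.get("rnn_params", rnn.RNNParams())
            nets = []
            for i in range(n_nets):
                t = rnn.train(rparams, seed=child_seed(seed, i))
                sel = rnn.roc_selectivity(t.weights, rparams, np.random.default_rng(child_seed(seed, 100 + i)))
                gh = rnn.estimate_gamma_rnn(t.weights, sel, rparams)
                nets.append({"trained": t, "selectivity": sel, "gamma_hat": gh})
            out.update(networks=nets)
        else:
            raise ValueError(f"unknown experiment {name!r}")
        manifest.status = "ok"
    except Exception:
        manifest.status = "failed"
        manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        if out_dir is not None:
            Path(out_dir).mkdir(parents=True, exist_ok=True)
            manifest.write(Path(out_dir) / f"{name}_manifest.json")
        raise
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for key, val in list(out.items()):
            if isinstance(val, pd.DataFrame):
                path = out_dir / f"{name}_{key}.csv"
                val.to_csv(path, index=False)
                manifest.register_output(path)
            elif isinstance(val, dict) and val and all(isinstance(v, pd.DataFrame) for v in val.values()):
                for sub, df in val.items():
                    path = out_dir / f"{name}_{key}_{sub}.csv"
                    df.to_csv(path, index=False)
                    manifest.register_output(path)
        manifest.write(out_dir / f"{name}_manifest.json")
    out["manifest"] = manifest
    return out
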