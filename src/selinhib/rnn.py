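"""Dale-constrained excitatory-inhibitory RNNs trained on the decision task.

Networks of N_E excitatory and N_I inhibitory rate units compare two noisy
input streams and report which has the higher mean by raising the matching
output.  Dale's law is enforced structurally: all six weight matrices are
non-negative and inhibitory contributions enter the dynamics with explicit
minus signs; negative entries are projected to zero after every optimizer
step, and recurrent diagonals are kept at zero.

The forward pass, backpropagation-through-time gradients and the
adaptive-moment (Adam) optimizer are implemented in numpy; the analytic
gradients are checked against central finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "RNNParams",
    "RNNWeights",
    "TrainedRNN",
    "init_rnn",
    "make_batch",
    "forward",
    "loss",
    "loss_and_grads",
    "train",
    "validate",
    "roc_selectivity",
    "estimate_gamma_rnn",
    "perturb_rnn",
    "save_checkpoint",
    "load_checkpoint",
]

RECURRENT_KEYS = ("EE", "EI", "IE", "II")
ALL_KEYS = RECURRENT_KEYS + ("in", "out")


@dataclass(frozen=True)
class RNNParams:
    """Architecture, task and training constants."""

    N_E: int = 100
    N_I: int = 25
    N_in: int = 2
    N_out: int = 2
    N_time: int = 60
    alpha_r: float = 0.2
    alpha_in: float = 0.2
    s_E: float = 1.0  # admissible range [0.5, 1.5]
    s_I: float = 1.0
    u0: float = 0.2
    mu: float = 3.2
    sigma_0r: float = 0.35
    sigma_0in: float = 0.05

    N_trial: int = 200
    f_catch: float = 0.5
    lambda_x: float = 0.1
    lambda_w: float = 1.0
    w_mu: float = 0.0375
    w_sigma: float = 0.5
    learning_rate: float = 0.01
    grad_clip: float = 1.0
    decision_threshold: float = 0.25
    stop_performance: float = 0.85

    stim_steps: int = 21
    min_pre: int = 10
    min_post: int = 10
    c_max: float = 20.0
    # c = 0 trials are ambiguous and excluded from the performance
    # denominator; set False for the all-trials variant
    exclude_zero_coherence: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.alpha_r <= 1 and 0 < self.alpha_in <= 1):
            raise ValueError("alpha_r and alpha_in must lie in (0, 1]")
        if not 0 <= self.f_catch <= 1:
            raise ValueError("f_catch must lie in [0, 1]")
        for n in ("N_E", "N_I", "N_in", "N_out", "N_time", "N_trial"):
            if getattr(self, n) <= 0:
                raise ValueError(f"{n} must be positive")
        if self.N_time < self.stim_steps + self.min_pre + self.min_post:
            raise ValueError("trial too short for stimulus plus margins")

    @property
    def theta(self) -> float:
        """Inhibitory initialization scale N_E s_E / (N_I s_I)."""
        return self.N_E * self.s_E / (self.N_I * self.s_I)

    @property
    def N(self) -> int:
        return self.N_E + self.N_I


class RNNWeights(dict):
    """The six non-negative weight matrices keyed EE, EI, IE, II, in, out.

    Orientation: W[post, pre].  'EE' is E->E (N_E x N_E), 'EI' is E->I
    (N_I x N_E), 'IE' is I->E (N_E x N_I), 'II' is I->I (N_I x N_I);
    'in' maps input streams to E units, 'out' E units to outputs.
    """

    def copy(self) -> "RNNWeights":
        return RNNWeights({k: v.copy() for k, v in self.items()})

    def check_invariants(self) -> None:
        for k in ALL_KEYS:
            if np.any(self[k] < 0):
                raise AssertionError(f"negative entries in W^{k}")
        for k in ("EE", "II"):
            if np.any(np.diagonal(self[k]) != 0):
                raise AssertionError(f"nonzero diagonal in W^{k}")


@dataclass
class TrainedRNN:
    weights: RNNWeights
    params: RNNParams
    seed: int
    epochs: int
    trials_seen: int
    reached_criterion: bool
    history: list = field(default_factory=list)


def init_rnn(params: RNNParams, seed: int) -> RNNWeights:
    """Gamma-distributed recurrent weights, normalized uniform in/out weights.

    Excitatory-origin matrices (EE, EI) use Gamma(shape=w_mu, scale=w_sigma);
    inhibitory-origin matrices (IE, II) use shape theta * w_mu to offset the
    count and excitability difference.  Input (output) weights are uniform,
    normalized to sum to one over units for each stream (output).
    """
    p = params
    rng = np.random.default_rng(seed)
    W = RNNWeights(
        EE=rng.gamma(p.w_mu, p.w_sigma, (p.N_E, p.N_E)),
        EI=rng.gamma(p.w_mu, p.w_sigma, (p.N_I, p.N_E)),
        IE=rng.gamma(p.theta * p.w_mu, p.w_sigma, (p.N_E, p.N_I)),
        II=rng.gamma(p.theta * p.w_mu, p.w_sigma, (p.N_I, p.N_I)),
    )
    W["in"] = rng.uniform(size=(p.N_E, p.N_in))
    W["out"] = rng.uniform(size=(p.N_out, p.N_E))
    np.fill_diagonal(W["EE"], 0.0)
    np.fill_diagonal(W["II"], 0.0)
    W["in"] /= W["in"].sum(axis=0, keepdims=True)
    W["out"] /= W["out"].sum(axis=1, keepdims=True)
    return W


def make_batch(params: RNNParams, n_trials: int, seed_or_rng, coherences=None, catch: bool = True):
    """Generate one batch of trials: inputs u, targets T, mask M, metadata.

    Stimulus occupies ``stim_steps`` consecutive steps with per-trial onset
    drawn uniformly subject to the pre/post margins.  Targets sit at the 0.2
    baseline and rise to 1 on the correct output from stimulus onset onward;
    the mask zeroes the error term during the stimulus (all ones on catch
    trials).  Non-catch trials split equally between choices with difficulty
    sampled uniformly from {2, 4, ..., c_max} (signed).
    """
    p = params
    rng = seed_or_rng if hasattr(seed_or_rng, "standard_normal") else np.random.default_rng(seed_or_rng)
    lo, hi = p.min_pre, p.N_time - p.stim_steps - p.min_post
    if hi < lo:
        raise ValueError("no feasible stimulus onset for this N_time")
    t_on = rng.integers(lo, hi + 1, size=n_trials)
    t_off = t_on + p.stim_steps

    if coherences is None:
        n_catch = int(round(n_trials * p.f_catch)) if catch else 0
        n_active = n_trials - n_catch
        half = n_active // 2
        pool = np.arange(2.0, p.c_max + 1e-9, 2.0)
        c = np.concatenate(
            [np.zeros(n_catch), rng.choice(pool, size=half), -rng.choice(pool, size=n_active - half)]
        )
        is_catch = np.concatenate([np.ones(n_catch, bool), np.zeros(n_active, bool)])
        perm = rng.permutation(n_trials)
        c, is_catch = c[perm], is_catch[perm]
    else:
        c = np.asarray(coherences, dtype=float)
        if len(c) != n_trials:
            raise ValueError("coherence list length must equal n_trials")
        is_catch = np.zeros(n_trials, bool)

    t = np.arange(p.N_time)
    stim = (t[None, :] >= t_on[:, None]) & (t[None, :] < t_off[:, None]) & ~is_catch[:, None]
    u = np.full((n_trials, p.N_time, p.N_in), p.u0)
    u[..., 0] += stim * (1.0 + p.mu * c[:, None] / 100.0)
    u[..., 1] += stim * (1.0 - p.mu * c[:, None] / 100.0)
    u += np.sqrt(2.0 / p.alpha_in) * p.sigma_0in * rng.standard_normal(u.shape)

    post = (t[None, :] >= t_on[:, None]) & ~is_catch[:, None]
    T = np.full((n_trials, p.N_time, p.N_out), 0.2)
    T[..., 0] = np.where(post & (c[:, None] > 0), 1.0, 0.2)
    T[..., 1] = np.where(post & (c[:, None] < 0), 1.0, 0.2)
    M = np.where(stim, 0.0, 1.0)
    M[is_catch] = 1.0
    return {"u": u, "T": T, "M": M, "c": c, "is_catch": is_catch, "t_on": t_on, "t_off": t_off}


def forward(weights: RNNWeights, params: RNNParams, batch, seed_or_rng, noise: bool = True, delta_I: float = 0.0):
    """Leaky rate dynamics; returns activations, rates, and outputs.

    ``delta_I`` adds a constant current to inhibitory units during each
    trial's stimulus steps (perturbation experiments).  Recurrent noise is
    scaled by sqrt(2 alpha_r) sigma_0r, input noise (already in the batch)
    by sqrt(2 / alpha_in) sigma_0in.
    """
    p = params
    u = batch["u"]
    rng = seed_or_rng if hasattr(seed_or_rng, "standard_normal") else np.random.default_rng(seed_or_rng)
    n, Nt, _ = u.shape
    sig = np.sqrt(2.0 * p.alpha_r) * p.sigma_0r
    stim_mask = None
    if delta_I != 0.0:
        t = np.arange(Nt)
        stim_mask = ((t[None, :] >= batch["t_on"][:, None]) & (t[None, :] < batch["t_off"][:, None]) & ~batch["is_catch"][:, None]).astype(float)

    xE = np.zeros((n, p.N_E))
    xI = np.zeros((n, p.N_I))
    xin = np.zeros((n, p.N_in))
    XE = np.empty((n, Nt, p.N_E))
    XI = np.empty((n, Nt, p.N_I))
    XIN = np.empty((n, Nt, p.N_in))
    for t_ in range(Nt):
        xin = (1.0 - p.alpha_in) * xin + p.alpha_in * u[:, t_]
        rE = p.s_E * np.maximum(xE, 0.0)
        rI = p.s_I * np.maximum(xI, 0.0)
        hE = rE @ weights["EE"].T - rI @ weights["IE"].T + xin @ weights["in"].T
        hI = rE @ weights["EI"].T - rI @ weights["II"].T
        if noise:
            hE = hE + sig * rng.standard_normal((n, p.N_E))
            hI = hI + sig * rng.standard_normal((n, p.N_I))
        if stim_mask is not None:
            hI = hI + delta_I * stim_mask[:, t_][:, None]
        xE = (1.0 - p.alpha_r) * xE + p.alpha_r * hE
        xI = (1.0 - p.alpha_r) * xI + p.alpha_r * hI
        if not (np.all(np.isfinite(xE)) and np.all(np.isfinite(xI))):
            raise FloatingPointError("non-finite activations during forward pass")
        XE[:, t_] = xE
        XI[:, t_] = xI
        XIN[:, t_] = xin
    RE = p.s_E * np.maximum(XE, 0.0)
    RI = p.s_I * np.maximum(XI, 0.0)
    Z = RE @ weights["out"].T
    return {"XE": XE, "XI": XI, "XIN": XIN, "RE": RE, "RI": RI, "Z": Z}


def loss(weights: RNNWeights, params: RNNParams, batch, fwd) -> float:
    """Masked MSE + L2 activity penalty + L1 weight penalty."""
    p = params
    n, Nt, _ = batch["u"].shape
    err = (batch["T"] - fwd["Z"]) * batch["M"][..., None]
    L = float((err**2).sum()) / (n * Nt * p.N_out)
    L += p.lambda_x / (p.N * n * Nt) * float((fwd["XE"] ** 2).sum() + (fwd["XI"] ** 2).sum())
    L += p.lambda_w / p.N**2 * sum(float(np.abs(weights[k]).sum()) for k in RECURRENT_KEYS)
    return L


def loss_and_grads(weights: RNNWeights, params: RNNParams, batch, seed_or_rng, noise: bool = True):
    """Loss and analytic BPTT gradients for all six matrices."""
    p = params
    fwd = forward(weights, params, batch, seed_or_rng, noise=noise)
    XE, XI, XIN, RE, RI, Z = (fwd[k] for k in ("XE", "XI", "XIN", "RE", "RI", "Z"))
    n, Nt, _ = batch["u"].shape
    L = loss(weights, params, batch, fwd)

    err = (batch["T"] - Z) * batch["M"][..., None]
    dZ = -2.0 * err / (n * Nt * p.N_out)
    dRE_out = dZ @ weights["out"]
    cx = 2.0 * p.lambda_x / (p.N * n * Nt)

    A = np.empty((n, Nt, p.N_E))
    B = np.empty((n, Nt, p.N_I))
    for t_ in range(Nt - 1, -1, -1):
        mE = (XE[:, t_] > 0) * p.s_E
        mI = (XI[:, t_] > 0) * p.s_I
        if t_ < Nt - 1:
            drE = p.alpha_r * (A[:, t_ + 1] @ weights["EE"] + B[:, t_ + 1] @ weights["EI"])
            drI = -p.alpha_r * (A[:, t_ + 1] @ weights["IE"] + B[:, t_ + 1] @ weights["II"])
            A[:, t_] = (1.0 - p.alpha_r) * A[:, t_ + 1] + (dRE_out[:, t_] + drE) * mE + cx * XE[:, t_]
            B[:, t_] = (1.0 - p.alpha_r) * B[:, t_ + 1] + drI * mI + cx * XI[:, t_]
        else:
            A[:, t_] = dRE_out[:, t_] * mE + cx * XE[:, t_]
            B[:, t_] = cx * XI[:, t_]

    REp = np.concatenate([np.zeros((n, 1, p.N_E)), RE[:, :-1]], axis=1)
    RIp = np.concatenate([np.zeros((n, 1, p.N_I)), RI[:, :-1]], axis=1)
    l1 = p.lambda_w / p.N**2
    g = RNNWeights()
    g["EE"] = p.alpha_r * np.einsum("nte,ntf->ef", A, REp) + l1 * np.sign(weights["EE"])
    g["IE"] = -p.alpha_r * np.einsum("nte,ntf->ef", A, RIp) + l1 * np.sign(weights["IE"])
    g["EI"] = p.alpha_r * np.einsum("nte,ntf->ef", B, REp) + l1 * np.sign(weights["EI"])
    g["II"] = -p.alpha_r * np.einsum("nte,ntf->ef", B, RIp) + l1 * np.sign(weights["II"])
    g["in"] = p.alpha_r * np.einsum("nte,ntf->ef", A, XIN)
    g["out"] = np.einsum("nto,nte->oe", dZ, RE)
    return L, g, fwd


def _project(W: RNNWeights) -> None:
    for k in ALL_KEYS:
        np.maximum(W[k], 0.0, out=W[k])
    np.fill_diagonal(W["EE"], 0.0)
    np.fill_diagonal(W["II"], 0.0)


def validate(weights: RNNWeights, params: RNNParams, seed_or_rng, n_trials: int = 100, delta_I: float = 0.0):
    """Task performance on a validation batch spanning all coherences.

    Coherences cycle through -c_max..c_max in steps of 2.  A decision is the
    first step after stimulus onset with |z1 - z2| above threshold; a trial
    is valid when at most 25% of pre-stimulus steps and at least 50% of
    post-stimulus steps are above threshold and a crossing occurred.
    Overall performance counts correct choices over all trials (c = 0
    excluded); accuracy/psychometric summaries use valid trials only.
    """
    p = params
    rng = seed_or_rng if hasattr(seed_or_rng, "standard_normal") else np.random.default_rng(seed_or_rng)
    levels = np.arange(-p.c_max, p.c_max + 1e-9, 2.0)
    cs = np.tile(levels, int(np.ceil(n_trials / len(levels))))[:n_trials]
    batch = make_batch(p, n_trials, rng, coherences=cs)
    fwd = forward(weights, p, batch, rng, delta_I=delta_I)
    dz = fwd["Z"][..., 0] - fwd["Z"][..., 1]
    above = np.abs(dz) > p.decision_threshold

    n = n_trials
    t_on, t_off = batch["t_on"], batch["t_off"]
    correct = np.zeros(n, bool)
    valid = np.zeros(n, bool)
    choice = np.zeros(n, int)
    dec_step = np.full(n, -1)
    for i in range(n):
        post_on = above[i, t_on[i]:]
        idx = np.flatnonzero(post_on)
        if len(idx):
            s = t_on[i] + idx[0]
            choice[i] = 1 if dz[i, s] > 0 else 2
            dec_step[i] = idx[0]
        pre_frac = above[i, : t_on[i]].mean() if t_on[i] > 0 else 0.0
        post = above[i, t_off[i]:]
        post_frac = post.mean() if len(post) else 0.0
        valid[i] = len(idx) > 0 and pre_frac <= 0.25 and post_frac >= 0.5
        want = 1 if cs[i] > 0 else 2
        correct[i] = valid[i] and cs[i] != 0 and choice[i] == want
    scored = cs != 0 if p.exclude_zero_coherence else np.ones(n, bool)
    performance = float(correct[scored].sum() / scored.sum())
    return {
        "performance": performance,
        "coherence": cs,
        "valid": valid,
        "choice": choice,
        "decision_step": dec_step,
        "correct": correct,
    }


def train(params: RNNParams, seed: int, max_epochs: int = 2000, callback=None) -> TrainedRNN:
    """Train to the stopping criterion with Adam and per-step Dale projection.

    Fresh random batches each epoch; validation after every epoch; stops
    when overall performance reaches ``stop_performance``.  Exactly
    reproducible from (params, seed): weights from seed, the data/noise
    stream from a generator derived from seed.
    """
    p = params
    W = init_rnn(p, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    m = {k: np.zeros_like(W[k]) for k in ALL_KEYS}
    v = {k: np.zeros_like(W[k]) for k in ALL_KEYS}
    b1, b2, eps = 0.9, 0.999, 1e-8
    lr = p.learning_rate
    history = []
    step = 0
    reached = False
    for epoch in range(max_epochs):
        batch = make_batch(p, p.N_trial, rng)
        L, g, _ = loss_and_grads(W, p, batch, rng)
        gn = np.sqrt(sum(float((g[k] ** 2).sum()) for k in ALL_KEYS))
        if gn > p.grad_clip:
            for k in ALL_KEYS:
                g[k] *= p.grad_clip / gn
        step += 1
        for k in ALL_KEYS:
            m[k] = b1 * m[k] + (1 - b1) * g[k]
            v[k] = b2 * v[k] + (1 - b2) * g[k] ** 2
            W[k] -= lr * (m[k] / (1 - b1**step)) / (np.sqrt(v[k] / (1 - b2**step)) + eps)
        _project(W)
        val = validate(W, p, rng)
        history.append({"epoch": epoch + 1, "loss": L, "performance": val["performance"], "trials": (epoch + 1) * p.N_trial})
        if callback is not None:
            callback(epoch, L, val["performance"])
        if val["performance"] >= p.stop_performance:
            reached = True
            break
    return TrainedRNN(
        weights=W,
        params=p,
        seed=seed,
        epochs=len(history),
        trials_seen=len(history) * p.N_trial,
        reached_criterion=reached,
        history=history,
    )


def roc_selectivity(
    weights: RNNWeights,
    params: RNNParams,
    seed_or_rng,
    n_eval_trials: int = 200,
    n_shuffles: int = 150,
    valid_only: bool = True,
):
    """Per-unit choice selectivity from the step after stimulus offset.

    For every unit, the AUC of decoding the network's choice from its
    activity at the single post-offset time step; a two-sided permutation
    test (label shuffles, 2.5% tails) flags significant units.  The
    selectivity index is |AUC - 0.5|.
    """
    p = params
    rng = seed_or_rng if hasattr(seed_or_rng, "standard_normal") else np.random.default_rng(seed_or_rng)
    levels = np.arange(-p.c_max, p.c_max + 1e-9, 2.0)
    cs = np.tile(levels, int(np.ceil(n_eval_trials / len(levels))))[:n_eval_trials]
    batch = make_batch(p, n_eval_trials, rng, coherences=cs)
    fwd = forward(weights, p, batch, rng)
    dz = fwd["Z"][..., 0] - fwd["Z"][..., 1]
    above = np.abs(dz) > p.decision_threshold

    acts = []
    labels = []
    for i in range(n_eval_trials):
        t_on, t_off = batch["t_on"][i], batch["t_off"][i]
        idx = np.flatnonzero(above[i, t_on:])
        if not len(idx):
            continue
        if valid_only:
            pre_frac = above[i, :t_on].mean() if t_on > 0 else 0.0
            post = above[i, t_off:]
            if pre_frac > 0.25 or (len(post) and post.mean() < 0.5):
                continue
        choice = 1 if dz[i, t_on + idx[0]] > 0 else 2
        acts.append(np.concatenate([fwd["RE"][i, t_off], fwd["RI"][i, t_off]]))
        labels.append(choice == 1)
    acts = np.asarray(acts)
    labels = np.asarray(labels)
    n1 = int(labels.sum())
    n2 = int((~labels).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two evaluation trials per choice")

    from scipy.stats import rankdata

    ranks = rankdata(acts, axis=0)
    auc = (ranks[labels].sum(axis=0) - n1 * (n1 + 1) / 2) / (n1 * n2)
    perms = np.stack([rng.permutation(labels) for _ in range(n_shuffles)]).astype(float)
    null = (perms @ ranks - n1 * (n1 + 1) / 2) / (n1 * n2)
    lo = np.percentile(null, 2.5, axis=0)
    hi = np.percentile(null, 97.5, axis=0)
    significant = (auc < lo) | (auc > hi)
    return {
        "auc": auc,
        "index": np.abs(auc - 0.5),
        "significant": significant,
        "preferred_choice": np.where(auc > 0.5, 1, 2),
        "n_eval_trials": int(len(labels)),
        "n_units_E": p.N_E,
        "n_units_I": p.N_I,
    }


def estimate_gamma_rnn(weights: RNNWeights, selectivity, params: RNNParams) -> dict:
    """Connection-specificity estimates from weights between selective units.

    For each directed class, gamma-hat = (<w+> - <w->)/(<w+> + <w->) where
    <w+> (<w->) averages weights between significantly selective units whose
    preferred choices match (differ), presynaptic preference against
    postsynaptic preference, self-connections excluded.  A class with a
    missing preference group on either side is reported as None.
    """
    p = params
    sig = selectivity["significant"]
    pref = selectivity["preferred_choice"]
    sigE, sigI = sig[: p.N_E], sig[p.N_E:]
    prefE, prefI = pref[: p.N_E], pref[p.N_E:]

    def gamma(W, post_sig, post_pref, pre_sig, pre_pref, exclude_diag):
        post_idx = np.flatnonzero(post_sig)
        pre_idx = np.flatnonzero(pre_sig)
        if len(post_idx) == 0 or len(pre_idx) == 0:
            return None
        sub = W[np.ix_(post_idx, pre_idx)]
        same = post_pref[post_idx][:, None] == pre_pref[pre_idx][None, :]
        keep = np.ones_like(same, dtype=bool)
        if exclude_diag:
            keep = post_idx[:, None] != pre_idx[None, :]
        wp_mask = same & keep
        wm_mask = ~same & keep
        if not wp_mask.any() or not wm_mask.any():
            return None
        wp = float(sub[wp_mask].mean())
        wm = float(sub[wm_mask].mean())
        if wp + wm == 0:
            return None
        return (wp - wm) / (wp + wm)

    return {
        "EE": gamma(weights["EE"], sigE, prefE, sigE, prefE, True),
        "EI": gamma(weights["EI"], sigI, prefI, sigE, prefE, False),
        "IE": gamma(weights["IE"], sigE, prefE, sigI, prefI, False),
        "II": gamma(weights["II"], sigI, prefI, sigI, prefI, True),
    }


def perturb_rnn(
    trained: TrainedRNN,
    deltas=(-1.0, -0.5, 0.0, 0.5, 1.0),
    n_trials: int = 200,
    seed: int = 0,
    common_random_numbers: bool = True,
):
    """Constant input to all inhibitory units during the stimulus period.

    Returns per-delta completion, accuracy and mean decision step deltas
    relative to delta = 0, with common random numbers across levels.
    """
    import pandas as pd

    p = trained.params
    rows = []
    ref = None
    for j, d in enumerate(deltas):
        rng = np.random.default_rng(np.random.SeedSequence([seed if common_random_numbers else seed + j, 3]))
        val = validate(trained.weights, p, rng, n_trials=n_trials, delta_I=d)
        valid = val["valid"]
        cs = val["coherence"]
        scored = (cs != 0) & valid
        acc = float(val["correct"][scored].sum() / max(scored.sum(), 1))
        steps = val["decision_step"][valid & (val["decision_step"] >= 0)]
        row = {
            "delta_I": d,
            "completion": float(valid.mean()),
            "accuracy": acc,
            "mean_decision_step": float(steps.mean()) if len(steps) else np.nan,
        }
        if d == 0.0:
            ref = row
        rows.append(row)
    if ref is None:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
        val = validate(trained.weights, p, rng, n_trials=n_trials, delta_I=0.0)
        valid = val["valid"]
        cs = val["coherence"]
        scored = (cs != 0) & valid
        ref = {
            "completion": float(valid.mean()),
            "accuracy": float(val["correct"][scored].sum() / max(scored.sum(), 1)),
            "mean_decision_step": float(val["decision_step"][valid & (val["decision_step"] >= 0)].mean()),
        }
    out = pd.DataFrame(rows)
    out["d_completion"] = out["completion"] - ref["completion"]
    out["d_accuracy"] = out["accuracy"] - ref["accuracy"]
    out["d_decision_step"] = out["mean_decision_step"] - ref["mean_decision_step"]
    return out


def save_checkpoint(trained: TrainedRNN, path: str | Path) -> None:
    """Portable checkpoint: weights + params + history (.npz with JSON sidecar)."""
    path = Path(path)
    np.savez(path, **{f"W_{k}": trained.weights[k] for k in ALL_KEYS})
    meta = {
        "params": asdict(trained.params),
        "seed": trained.seed,
        "epochs": trained.epochs,
        "trials_seen": trained.trials_seen,
        "reached_criterion": trained.reached_criterion,
        "history": trained.history,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> TrainedRNN:
    path = Path(path)
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    W = RNNWeights({k: data[f"W_{k}"] for k in ALL_KEYS})
    return TrainedRNN(
        weights=W,
        params=RNNParams(**meta["params"]),
        seed=meta["seed"],
        epochs=meta["epochs"],
        trials_seen=meta["trials_seen"],
        reached_criterion=meta["reached_criterion"],
        history=meta["history"],
    )
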