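"""Fixed points, stability, and bifurcation structure of the noiseless circuit.

A decision-competent ("good") circuit has eight fixed points: in the
unstimulated phase plane a symmetric low-activity attractor, two mirror
working-memory attractors and two mirror saddles; in the stimulated plane
(zero-coherence stimulus on) two mirror choice attractors separated by one
symmetric saddle.  The saddle's positive Jacobian eigenvalue sets the slow
time constant ``tau_slow = 1 / lambda_plus`` that governs evidence
integration.

Root finding uses a damped Gauss-Newton (Levenberg-style) iteration,
vectorized over a multistart grid and, for parameter scans, over parameter
points as well; every candidate root is re-verified by substitution at
tolerance 1e-6 and deduplicated at radius 1e-4 in S-space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .couplings import DerivedCouplings, derive_couplings
from .meanfield import StimulusSpec, _transfer_deriv, transfer_rate
from .params import CircuitParams

__all__ = [
    "FixedPoint",
    "CircuitClassification",
    "find_fixed_points",
    "linearize",
    "label_fixed_points",
    "classify_circuit",
    "scan_specificity",
    "bifurcation_sweep",
]

RESIDUAL_TOL = 1e-6
DEDUP_RADIUS = 1e-4


@dataclass(frozen=True)
class FixedPoint:
    S: tuple[float, float]
    rates: tuple[float, float]
    residual: float
    eigenvalues: tuple[complex, complex]
    stability: str  # 'attractor' | 'saddle' | 'repeller'
    tau_slow: float | None

    @property
    def is_symmetric(self) -> bool:
        return abs(self.rates[0] - self.rates[1]) < 0.1  # Hz


@dataclass(frozen=True)
class CircuitClassification:
    low_state_attractor: bool
    wm_attractor_pair: bool
    unstim_saddle_pair: bool
    choice_attractor_pair: bool
    stim_saddle: bool
    is_good_decision_circuit: bool
    indeterminate: bool = False
    n_unstim: tuple[int, int, int] = (0, 0, 0)  # attractors, saddles, repellers
    n_stim: tuple[int, int, int] = (0, 0, 0)


def _default_starts(n_grid: int = 21) -> np.ndarray:
    g = np.linspace(0.0, 1.0, n_grid)
    starts = np.stack(np.meshgrid(g, g), axis=-1).reshape(-1, 2)
    canon = np.array(
        [[0, 0], [1, 1], [0, 1], [1, 0], [0.5, 0.5], [0.5, 0], [0, 0.5], [1, 0.5], [0.5, 1]],
        dtype=float,
    )
    return np.concatenate([starts, canon])


def _field_and_jac(S1, S2, al1, al2, I0, Ist1, Ist2, params: CircuitParams):
    """Vector field and analytic Jacobian entries, broadcast over inputs."""
    p = params
    g = p.gamma_kinetic
    x1 = al1 * S1 + al2 * S2 + I0 + Ist1
    x2 = al1 * S2 + al2 * S1 + I0 + Ist2
    r1 = transfer_rate(x1, p.gain)
    r2 = transfer_rate(x2, p.gain)
    dr1 = _transfer_deriv(x1, p.gain)
    dr2 = _transfer_deriv(x2, p.gain)
    F1 = -S1 / p.tau_NMDA + (1.0 - S1) * g * r1
    F2 = -S2 / p.tau_NMDA + (1.0 - S2) * g * r2
    J11 = -1.0 / p.tau_NMDA - g * r1 + (1.0 - S1) * g * dr1 * al1
    J12 = (1.0 - S1) * g * dr1 * al2
    J21 = (1.0 - S2) * g * dr2 * al2
    J22 = -1.0 / p.tau_NMDA - g * r2 + (1.0 - S2) * g * dr2 * al1
    return F1, F2, J11, J12, J21, J22


def _solve_batched(al1, al2, I0, Ist1, Ist2, params: CircuitParams, starts: np.ndarray, max_iter: int = 80):
    """Damped Gauss-Newton from every start; returns converged (S1, S2).

    All coupling arrays broadcast against the leading axis; ``starts`` is
    (k, 2).  Returns flat arrays S1, S2, ok with shape (..., k).
    """
    al1, al2, I0 = np.broadcast_arrays(np.atleast_1d(al1), np.atleast_1d(al2), np.atleast_1d(I0))
    n_pts = al1.shape[0]
    k = starts.shape[0]
    S1 = np.tile(starts[:, 0], n_pts).reshape(n_pts, k)
    S2 = np.tile(starts[:, 1], n_pts).reshape(n_pts, k)
    A1 = al1[:, None]
    A2 = al2[:, None]
    B = I0[:, None]
    mu = np.full((n_pts, k), 1e-8)
    for _ in range(max_iter):
        F1, F2, J11, J12, J21, J22 = _field_and_jac(S1, S2, A1, A2, B, Ist1, Ist2, params)
        # Levenberg step: (J^T J + mu I) dS = -J^T F, closed form for 2x2
        g1 = J11 * F1 + J21 * F2
        g2 = J12 * F1 + J22 * F2
        a = J11 * J11 + J21 * J21 + mu
        bm = J11 * J12 + J21 * J22
        c = J12 * J12 + J22 * J22 + mu
        det = a * c - bm * bm
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        d1 = -(c * g1 - bm * g2) / det
        d2 = -(a * g2 - bm * g1) / det
        step = np.hypot(d1, d2)
        lim = np.where(step > 0.25, 0.25 / np.where(step == 0, 1, step), 1.0)
        S1 = np.clip(S1 + d1 * lim, -0.05, 1.05)
        S2 = np.clip(S2 + d2 * lim, -0.05, 1.05)
    F1, F2, *_ = _field_and_jac(S1, S2, A1, A2, B, Ist1, Ist2, params)
    ok = (np.maximum(np.abs(F1), np.abs(F2)) <= RESIDUAL_TOL) & (S1 > -1e-6) & (S1 < 1 + 1e-6) & (S2 > -1e-6) & (S2 < 1 + 1e-6)
    return S1, S2, ok


def _dedup(points: np.ndarray, radius: float = DEDUP_RADIUS) -> np.ndarray:
    """Cluster candidate roots; returns representatives."""
    if len(points) == 0:
        return points
    reps: list[np.ndarray] = []
    for pt in points:
        if not any(np.hypot(*(pt - r)) < radius for r in reps):
            reps.append(pt)
    return np.array(reps)


def _eig2(J11, J12, J21, J22) -> tuple[complex, complex]:
    tr = J11 + J22
    det = J11 * J22 - J12 * J21
    disc = tr * tr - 4.0 * det
    sq = np.sqrt(complex(disc))
    return ((tr + sq) / 2.0, (tr - sq) / 2.0)


def linearize(params: CircuitParams, point, couplings: DerivedCouplings | None = None, stim: StimulusSpec | None = None, nu0_I: float | None = None):
    """Analytic Jacobian at a fixed point with stability classification.

    Returns (J, eigenvalues, stability, tau_slow).  Rejects points that are
    not roots of the noiseless dynamics at the residual tolerance.
    """
    c = couplings if couplings is not None else derive_couplings(params, nu0_I=nu0_I)
    Ist1 = Ist2 = 0.0
    if stim is not None:
        base = params.J_AMPA_ext * stim.mu
        Ist1 = base * (1.0 - stim.coherence_c / 100.0)
        Ist2 = base * (1.0 + stim.coherence_c / 100.0)
    S1, S2 = float(point[0]), float(point[1])
    F1, F2, J11, J12, J21, J22 = _field_and_jac(S1, S2, c.alpha1, c.alpha2, c.I0_1, Ist1, Ist2, params)
    if max(abs(float(F1)), abs(float(F2))) > RESIDUAL_TOL:
        raise ValueError(f"point {point} is not a fixed point (residual {max(abs(float(F1)), abs(float(F2))):.2e})")
    J = np.array([[float(J11), float(J12)], [float(J21), float(J22)]])
    ev = _eig2(*J.ravel())
    reals = sorted((e.real for e in ev), reverse=True)
    if reals[0] < 0:
        stability = "attractor"
    elif reals[0] > 0 and reals[1] < 0:
        stability = "saddle"
    else:
        stability = "repeller"
    tau_slow = 1.0 / reals[0] if stability == "saddle" else None
    return J, ev, stability, tau_slow


def find_fixed_points(
    params: CircuitParams,
    stim: StimulusSpec | None = None,
    couplings: DerivedCouplings | None = None,
    nu0_I: float | None = None,
    n_grid: int = 21,
) -> list[FixedPoint]:
    """All fixed points of the noiseless system, classified.

    ``stim=None`` analyses the unstimulated plane; passing a StimulusSpec
    holds its currents on permanently (the standard phase-plane convention
    for the stimulated system).
    """
    c = couplings if couplings is not None else derive_couplings(params, nu0_I=nu0_I)
    Ist1 = Ist2 = 0.0
    if stim is not None:
        base = params.J_AMPA_ext * stim.mu
        Ist1 = base * (1.0 - stim.coherence_c / 100.0)
        Ist2 = base * (1.0 + stim.coherence_c / 100.0)
    starts = _default_starts(n_grid)
    S1, S2, ok = _solve_batched(c.alpha1, c.alpha2, c.I0_1, Ist1, Ist2, params, starts)
    pts = _dedup(np.stack([np.clip(S1[0][ok[0]], 0, 1), np.clip(S2[0][ok[0]], 0, 1)], axis=-1))
    out = []
    for pt in pts:
        F1, F2, J11, J12, J21, J22 = _field_and_jac(pt[0], pt[1], c.alpha1, c.alpha2, c.I0_1, Ist1, Ist2, params)
        res = max(abs(float(F1)), abs(float(F2)))
        ev = _eig2(float(J11), float(J12), float(J21), float(J22))
        reals = sorted((e.real for e in ev), reverse=True)
        if reals[0] < 0:
            stability = "attractor"
        elif reals[0] > 0 and reals[1] < 0:
            stability = "saddle"
        else:
            stability = "repeller"
        x1 = c.alpha1 * pt[0] + c.alpha2 * pt[1] + c.I0_1 + Ist1
        x2 = c.alpha1 * pt[1] + c.alpha2 * pt[0] + c.I0_1 + Ist2
        out.append(
            FixedPoint(
                S=(float(pt[0]), float(pt[1])),
                rates=(float(transfer_rate(x1, params.gain)), float(transfer_rate(x2, params.gain))),
                residual=res,
                eigenvalues=ev,
                stability=stability,
                tau_slow=1.0 / reals[0] if stability == "saddle" else None,
            )
        )
    out.sort(key=lambda f: (f.S[0] + f.S[1], f.S[0] - f.S[1]))
    return out


def label_fixed_points(unstim: list[FixedPoint], stim: list[FixedPoint], rate_threshold: float = 15.0, symmetry_tol: float = 0.1) -> CircuitClassification:
    """Taxonomy of the eight decision fixed points.

    Unstimulated plane: a symmetric low-rate attractor, a mirror pair of
    asymmetric working-memory attractors, and a mirror pair of saddles.
    Stimulated plane (c = 0): a mirror pair of choice attractors and one
    symmetric saddle.  Ambiguous configurations (e.g. two symmetric
    attractors in one plane) are flagged indeterminate, never silently
    resolved.
    """

    def split(fps):
        att = [f for f in fps if f.stability == "attractor"]
        sad = [f for f in fps if f.stability == "saddle"]
        rep = [f for f in fps if f.stability == "repeller"]
        return att, sad, rep

    def symmetric(f: FixedPoint) -> bool:
        return abs(f.rates[0] - f.rates[1]) < symmetry_tol

    def mirror_paired(fs: list[FixedPoint]) -> bool:
        if len(fs) != 2:
            return False
        a, b = fs
        return np.hypot(a.S[0] - b.S[1], a.S[1] - b.S[0]) < 10 * DEDUP_RADIUS

    u_att, u_sad, _u_rep = split(unstim)
    s_att, s_sad, _s_rep = split(stim)

    indeterminate = False

    sym_att = [f for f in u_att if symmetric(f)]
    asym_att = [f for f in u_att if not symmetric(f)]
    low_state = len(sym_att) == 1 and all(r < rate_threshold for r in sym_att[0].rates)
    if len(sym_att) > 1:
        indeterminate = True
    wm_pair = mirror_paired(asym_att)
    unstim_sad_pair = mirror_paired([f for f in u_sad if not symmetric(f)]) and len(u_sad) == 2

    s_sym_sad = [f for f in s_sad if symmetric(f)]
    choice_pair = mirror_paired([f for f in s_att if not symmetric(f)]) and len(s_att) == 2
    stim_saddle = len(s_sym_sad) == 1 and len(s_sad) == 1

    good = (
        low_state
        and wm_pair
        and unstim_sad_pair
        and choice_pair
        and stim_saddle
        and (len(u_att), len(u_sad)) == (3, 2)
        and (len(s_att), len(s_sad)) == (2, 1)
        and not indeterminate
    )
    return CircuitClassification(
        low_state_attractor=low_state,
        wm_attractor_pair=wm_pair,
        unstim_saddle_pair=unstim_sad_pair,
        choice_attractor_pair=choice_pair,
        stim_saddle=stim_saddle,
        is_good_decision_circuit=good,
        indeterminate=indeterminate,
        n_unstim=(len(u_att), len(u_sad), len(_u_rep)),
        n_stim=(len(s_att), len(s_sad), len(_s_rep)),
    )


def classify_circuit(params: CircuitParams, mu: float = 40.0, **kwargs) -> CircuitClassification:
    """find_fixed_points on both planes (c = 0) followed by labeling."""
    unstim = find_fixed_points(params, **kwargs)
    stim = find_fixed_points(params, stim=StimulusSpec(mu=mu, coherence_c=0.0), **kwargs)
    return label_fixed_points(unstim, stim)


def _census_signature(al1, al2, I0, Ist, params, starts, chunk=256):
    """Vectorized (n_attractor, n_saddle, n_total) census per parameter point."""
    al1 = np.atleast_1d(np.asarray(al1, dtype=float))
    al2 = np.atleast_1d(np.asarray(al2, dtype=float))
    I0 = np.broadcast_to(np.atleast_1d(I0), al1.shape)
    n = al1.shape[0]
    sig = np.zeros((n, 3), dtype=int)
    roots_per_point: list[np.ndarray] = []
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        S1, S2, ok = _solve_batched(al1[lo:hi], al2[lo:hi], I0[lo:hi], Ist, Ist, params, starts)
        for i in range(hi - lo):
            pts = _dedup(np.stack([np.clip(S1[i][ok[i]], 0, 1), np.clip(S2[i][ok[i]], 0, 1)], axis=-1))
            roots_per_point.append(pts)
            if len(pts) == 0:
                continue
            _, _, J11, J12, J21, J22 = _field_and_jac(pts[:, 0], pts[:, 1], al1[lo + i], al2[lo + i], I0[lo + i], Ist, Ist, params)
            tr = J11 + J22
            det = J11 * J22 - J12 * J21
            n_att = int(np.sum((det > 0) & (tr < 0)))
            n_sad = int(np.sum(det < 0))
            sig[lo + i] = (n_att, n_sad, len(pts))
    return sig, roots_per_point


def scan_specificity(
    params: CircuitParams,
    gamma_EE_grid,
    gamma_EI_grid,
    gamma_IE_grid,
    mu: float = 40.0,
    rate_threshold: float = 15.0,
    progress: bool = False,
) -> pd.DataFrame:
    """Classify every circuit on a 3-D specificity grid.

    Returns one row per (gamma_EE, gamma_EI, gamma_IE) with the full flag
    set, the fixed-point counts in both planes, and the inhibitory
    specificity index gamma_EI * gamma_IE.
    """
    gEE = np.asarray(gamma_EE_grid, dtype=float)
    gEI = np.asarray(gamma_EI_grid, dtype=float)
    gIE = np.asarray(gamma_IE_grid, dtype=float)
    EE, EI, IE = np.meshgrid(gEE, gEI, gIE, indexing="ij")
    EE, EI, IE = EE.ravel(), EI.ravel(), IE.ravel()

    base = derive_couplings(params)
    # coupling structure: alpha1a scales with (1 + gEE); disynaptic addends
    # with the w+/- weight products (exact, reusing derive_couplings per
    # gamma would be equivalent but ~1000x slower)
    a1a_unit = base.alpha1_components[0] / (1.0 + params.specificity.gamma_EE)
    D = -base.alpha1_components[3]
    al1 = params.lambda_1 * (a1a_unit * (1.0 + EE) - D * ((1.0 + EI) * (1.0 + IE) + (1.0 - EI) * (1.0 - IE) + 1.0))
    al2 = params.lambda_2 * (a1a_unit * (1.0 - EE) - D * ((1.0 - EI) * (1.0 + IE) + (1.0 + EI) * (1.0 - IE) + 1.0))
    I0 = base.I0_1
    Ist = params.J_AMPA_ext * mu

    starts = _default_starts()
    rows = []
    sig_u, roots_u = _census_signature(al1, al2, I0, 0.0, params, starts)
    sig_s, roots_s = _census_signature(al1, al2, I0, Ist, params, starts)

    for i in range(len(EE)):
        p_i = params.with_specificity(gamma_EE=float(EE[i]), gamma_EI=float(EI[i]), gamma_IE=float(IE[i]))
        good = bool(
            tuple(sig_u[i][:2]) == (3, 2)
            and tuple(sig_s[i][:2]) == (2, 1)
            and sig_u[i][2] == 5
            and sig_s[i][2] == 3
        )
        if good:
            # verify the full taxonomy (mirror pairing, low state) on candidates
            cls = classify_circuit(p_i, mu=mu)
            good = cls.is_good_decision_circuit
        rows.append(
            {
                "gamma_EE": EE[i],
                "gamma_EI": EI[i],
                "gamma_IE": IE[i],
                "specificity_index": EI[i] * IE[i],
                "n_unstim_attractors": sig_u[i][0],
                "n_unstim_saddles": sig_u[i][1],
                "n_unstim": sig_u[i][2],
                "n_stim_attractors": sig_s[i][0],
                "n_stim_saddles": sig_s[i][1],
                "n_stim": sig_s[i][2],
                "is_good_decision_circuit": good,
            }
        )
        if progress and (i + 1) % 500 == 0:
            print(f"scan: {i + 1}/{len(EE)} points")
    return pd.DataFrame(rows)


def bifurcation_sweep(
    params: CircuitParams,
    param_name: str,
    values,
    stim: StimulusSpec | None = None,
    bracket_tol: float = 1e-4,
) -> tuple[pd.DataFrame, list[dict]]:
    """Track fixed-point branches along a parameter path.

    ``param_name`` is one of ``gamma_IE``, ``specificity_index`` (swept via
    gamma_IE at fixed gamma_EI) or ``nu0_I``.  Returns (branch table,
    events); events record census-signature changes bracketed to
    ``bracket_tol`` by bisection, which covers branch birth/death and
    stability changes (saddle-node, saddle-to-attractor transitions,
    working-memory merges).
    """
    values = np.asarray(values, dtype=float)
    if np.any(np.diff(values) <= 0) and np.any(np.diff(values) >= 0) and not (np.all(np.diff(values) > 0) or np.all(np.diff(values) < 0)):
        raise ValueError("parameter path must be monotone")

    def params_at(v: float) -> CircuitParams:
        if param_name == "gamma_IE":
            return params.with_specificity(gamma_IE=v)
        if param_name == "specificity_index":
            gEI = params.specificity.gamma_EI
            if gEI == 0:
                raise ValueError("specificity_index sweep requires gamma_EI != 0")
            return params.with_specificity(gamma_IE=v / gEI)
        if param_name == "nu0_I":
            return params.replace(nu0_I=v)
        raise ValueError(f"unknown sweep parameter {param_name!r}")

    rows = []
    signatures = []
    prev_pts: np.ndarray | None = None
    branch_ids: list[int] = []
    next_branch = 0
    for v in values:
        fps = find_fixed_points(params_at(v), stim=stim)
        pts = np.array([f.S for f in fps]) if fps else np.empty((0, 2))
        # nearest-neighbor branch linking
        ids = []
        for pt in pts:
            if prev_pts is not None and len(prev_pts):
                dists = np.hypot(*(prev_pts - pt).T)
                j = int(np.argmin(dists))
                if dists[j] < 0.15:
                    ids.append(branch_ids[j])
                    continue
            ids.append(next_branch)
            next_branch += 1
        prev_pts, branch_ids = pts, ids
        sig = (
            sum(f.stability == "attractor" for f in fps),
            sum(f.stability == "saddle" for f in fps),
            len(fps),
        )
        signatures.append(sig)
        for f, bid in zip(fps, ids):
            rows.append(
                {
                    "param": param_name,
                    "value": v,
                    "branch": bid,
                    "S1": f.S[0],
                    "S2": f.S[1],
                    "r1": f.rates[0],
                    "r2": f.rates[1],
                    "stability": f.stability,
                    "tau_slow": f.tau_slow if f.tau_slow is not None else np.nan,
                }
            )

    events = []
    for i in range(len(values) - 1):
        if signatures[i] != signatures[i + 1]:
            lo, hi = float(values[i]), float(values[i + 1])
            sig_lo = signatures[i]
            while abs(hi - lo) > bracket_tol:
                mid = 0.5 * (lo + hi)
                fps = find_fixed_points(params_at(mid), stim=stim)
                sig_mid = (
                    sum(f.stability == "attractor" for f in fps),
                    sum(f.stability == "saddle" for f in fps),
                    len(fps),
                )
                if sig_mid == sig_lo:
                    lo = mid
                else:
                    hi = mid
            events.append(
                {
                    "param": param_name,
                    "bracket": (lo, hi),
                    "signature_before": signatures[i],
                    "signature_after": signatures[i + 1],
                }
            )
    return pd.DataFrame(rows), events
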