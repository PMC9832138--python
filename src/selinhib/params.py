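"""Circuit parameters for the two-variable mean-field decision model.

The model describes two choice-selective excitatory populations whose slow
NMDA gating variables ``S1, S2`` carry the circuit state, embedded in a
six-population circuit (selective/nonselective E and I pools).  Connection
specificity between choice-selective populations is parameterized per
connection class by ``gamma`` in [-1, 1]: positive gamma strengthens
connections between populations with the *same* choice preference
(ipsispecific for the I->E class), negative gamma strengthens connections
between populations with *opposite* preference (contraspecific).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "SpecificityParams",
    "TrialSchedule",
    "CircuitParams",
    "specificity_to_weights",
    "gamma_from_weights",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class SpecificityParams:
    """Connection-specificity parameters for the three connection classes.

    ``gamma_EE`` and ``gamma_EI`` are kept non-negative: recurrent excitatory
    feedback and the inheritance of choice selectivity by inhibitory neurons
    both require same-preference biased connections.  ``gamma_IE`` is signed;
    its sign selects the inhibitory motif (ipsi- vs contraspecific).
    """

    gamma_EE: float = 0.32
    gamma_EI: float = 0.25
    gamma_IE: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma_EE <= 1.0:
            raise ValueError(f"gamma_EE must be in [0, 1], got {self.gamma_EE}")
        if not 0.0 <= self.gamma_EI <= 1.0:
            raise ValueError(f"gamma_EI must be in [0, 1], got {self.gamma_EI}")
        if not -1.0 <= self.gamma_IE <= 1.0:
            raise ValueError(f"gamma_IE must be in [-1, 1], got {self.gamma_IE}")

    @property
    def specificity_index(self) -> float:
        """Inhibitory specificity index gamma_EI * gamma_IE (sign = motif)."""
        return self.gamma_EI * self.gamma_IE


@dataclass(frozen=True)
class TrialSchedule:
    """Trial epoch durations in seconds (pre-stimulus, stimulus, delay)."""

    pre: float = 0.5
    stim: float = 1.0
    post: float = 1.0

    def __post_init__(self) -> None:
        if min(self.pre, self.stim, self.post) < 0:
            raise ValueError("epoch durations must be non-negative")
        if self.stim <= 0:
            raise ValueError("stimulus epoch must have positive duration")

    @property
    def total(self) -> float:
        return self.pre + self.stim + self.post


@dataclass(frozen=True)
class CircuitParams:
    """All physiological constants of the two-variable circuit.

    Units follow the conventions of the field: time constants in seconds,
    rates in Hz, potentials in mV, conductances in uS, currents in nA.
    The transfer-gain triple ``(a, b, d)`` is for the excitatory
    current-to-rate function; ``gamma_kinetic`` converts presynaptic firing
    to NMDA-channel opening.
    """

    specificity: SpecificityParams = field(default_factory=SpecificityParams)
    # fraction of E (and I) neurons per choice-selective population; the
    # canonical reduced model uses the midpoint of the admissible range
    f: float = 0.15
    # baseline drive to inhibitory neurons, Hz; 11.5 = low-inhibition
    # (competition-dominated) operating point
    nu0_I: float = 11.5

    # population sizes
    N_E: int = 1600
    N_I: int = 400
    N_ext: int = 800
    N_s: int = 2

    # synaptic time constants, s
    tau_NMDA: float = 0.1
    tau_AMPA: float = 0.002
    tau_GABA: float = 0.005

    # firing-rate -> NMDA activation kinetic factor
    gamma_kinetic: float = 0.641

    # inhibitory f-I linearization: rate = (c_I * I - I_mI) / g_I2
    I_mI: float = 177.0
    c_I: float = 615.0
    g_I2: float = 2.0

    # background input rates, Hz
    nu_ext: float = 3.0
    nu_3_in: float = 2.0

    # potentials, mV
    V_E: float = -53.4
    V_I: float = -52.1
    E_E: float = 0.0
    E_I: float = -70.0

    # maximum conductances, uS
    g_E_rec_NMDA: float = 1.95e-4
    g_I_rec_NMDA: float = 1.02e-4
    g_E_rec_GABA: float = 0.130
    g_I_rec_GABA: float = 0.0084

    g_E_ext_AMPA: float = 2.1e-3
    g_I_ext_AMPA: float = 1.62e-3

    # external stimulus current per unit input rate, nA/Hz
    J_AMPA_ext: float = 5.2e-4

    # reduction scaling factors
    lambda_1: float = 1.6719
    lambda_2: float = 1.8844
    lambda_I: float = 0.9229

    # excitatory transfer gain: a [1/nC], b [Hz], d [s]
    a: float = 270.0
    b: float = 108.0
    d: float = 0.154

    # integration
    noise_sd: float = 0.02
    dt: float = 0.002
    # 'white_amplitude': noise_sd is the unit-intensity white-noise amplitude
    # of the OU input (stationary sd = noise_sd/sqrt(2 - dt/tau_AMPA));
    # 'stationary_sd': the OU process is rescaled so its stationary sd equals
    # noise_sd exactly.
    noise_convention: str = "white_amplitude"
    # report rates as Phi(deterministic drive); the noise current always
    # drives the S dynamics.  See docs/methods.md.
    rates_include_noise: bool = False

    schedule: TrialSchedule = field(default_factory=TrialSchedule)
    # initial NMDA activation, inside the basin of the low-activity attractor
    S_init: float = 0.1

    def __post_init__(self) -> None:
        if not 0.13 <= self.f <= 0.2:
            raise ValueError(f"f must be in [0.13, 0.2], got {self.f}")
        if 1.0 - self.N_s * self.f <= 0:
            raise ValueError("nonselective pool must be nonempty: N_s * f < 1")
        if not 9.0 <= self.nu0_I <= 16.0:
            raise ValueError(f"nu0_I must be in [9, 16], got {self.nu0_I}")
        for name in ("tau_NMDA", "tau_AMPA", "tau_GABA", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("N_E", "N_I", "N_ext", "N_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.noise_convention not in ("white_amplitude", "stationary_sd"):
            raise ValueError(f"unknown noise convention {self.noise_convention!r}")

    # -- convenience constructors -------------------------------------------------

    def with_specificity(
        self,
        gamma_EE: float | None = None,
        gamma_EI: float | None = None,
        gamma_IE: float | None = None,
    ) -> "CircuitParams":
        spec = self.specificity
        new = SpecificityParams(
            gamma_EE=spec.gamma_EE if gamma_EE is None else gamma_EE,
            gamma_EI=spec.gamma_EI if gamma_EI is None else gamma_EI,
            gamma_IE=spec.gamma_IE if gamma_IE is None else gamma_IE,
        )
        return dataclasses.replace(self, specificity=new)

    def replace(self, **kwargs: Any) -> "CircuitParams":
        return dataclasses.replace(self, **kwargs)

    @property
    def gain(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.d)


def specificity_to_weights(gamma: float, N_s: int = 2, w_base: float = 1.0) -> tuple[float, float]:
    """Map a specificity parameter to (same, opposite) connection weights.

    The intermediate weight ``w_hat = N_s * w_base / (N_s + gamma * (2 - N_s))``
    guarantees that the total input weight received by each population is
    independent of gamma; ``w_plus = w_hat * (1 + gamma)`` connects populations
    with the same choice preference, ``w_minus = w_hat * (1 - gamma)`` with the
    opposite preference.  For ``N_s = 2`` the normalization reduces to
    ``w_hat = w_base``.
    """
    if not -1.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [-1, 1], got {gamma}")
    if N_s < 2:
        raise ValueError("at least two competing selective populations required")
    w_hat = N_s * w_base / (N_s + gamma * (2 - N_s))
    return w_hat * (1.0 + gamma), w_hat * (1.0 - gamma)


def gamma_from_weights(w_plus: float, w_minus: float) -> float:
    """Normalized same/opposite weight contrast (w+ - w-)/(w+ + w-)."""
    return (w_plus - w_minus) / (w_plus + w_minus)


# -- configuration files ----------------------------------------------------------

_SCHEDULE_KEYS = ("pre", "stim", "post")
_SPEC_KEYS = ("gamma_EE", "gamma_EI", "gamma_IE")


def params_to_dict(params: CircuitParams) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for f_ in dataclasses.fields(CircuitParams):
        v = getattr(params, f_.name)
        if f_.name == "specificity":
            for k in _SPEC_KEYS:
                out[k] = getattr(v, k)
        elif f_.name == "schedule":
            out["schedule"] = {k: getattr(v, k) for k in _SCHEDULE_KEYS}
        else:
            out[f_.name] = v
    return out


def params_from_dict(data: dict[str, Any]) -> CircuitParams:
    data = dict(data)
    spec = SpecificityParams(**{k: data.pop(k) for k in _SPEC_KEYS if k in data})
    sched_data = data.pop("schedule", None)
    sched = TrialSchedule(**sched_data) if sched_data else TrialSchedule()
    known = {f_.name for f_ in dataclasses.fields(CircuitParams)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return CircuitParams(specificity=spec, schedule=sched, **data)


def load_config(path: str | Path) -> CircuitParams:
    """Read a YAML or JSON config file mirroring the parameter-table names."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return params_from_dict(data)


def save_config(params: CircuitParams, path: str | Path) -> None:
    path = Path(path)
    data = params_to_dict(params)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
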