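"""Reduction of the six-population circuit to effective two-variable couplings.

The circuit's full connectivity is collapsed into three quantities entering
the input current of each selective excitatory population,

    x_i = alpha_1 * S_i + alpha_2 * S_j + I_0 + I_stim,i + I_eta,i ,

where ``alpha_1`` collects every pathway by which a population's activity
feeds back onto itself (direct self-excitation plus the three disynaptic
routes through same-preference, opposite-preference and nonselective
inhibitory populations), ``alpha_2`` the pathways onto the competing
population, and ``I_0`` the activity-independent background.  Each alpha is a
scaled sum of four addends (a: direct E->E; b/c: disynaptic through the
same/opposite-preference inhibitory population; d: through nonselective
inhibition), with the inhibitory routes written as products of the E->I drive
and the I->E current per unit inhibitory rate.

Calibration.  The printed physiological constants do not determine the
magnitude of the disynaptic inhibitory routes or the background current
self-consistently (see docs/methods.md for the full analysis).  Both are
anchored to the canonical reduced two-variable decision model this circuit
generalizes: at the reference specificity (gamma_EE = 0.32, gamma_IE = 0) the
net couplings equal the canonical J11 = 0.2609 nA and -J12 = -0.0497 nA, a
condition the printed scaling factors lambda_1 and lambda_2 satisfy to 0.5%
simultaneously; the background current equals the canonical 0.3255 nA at the
reference baseline drive nu0_I = 11.5 Hz and maps the admissible baseline
range [9, 16] Hz onto the decision-competent window (slope 0.004 nA/Hz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import CircuitParams, specificity_to_weights

__all__ = ["DerivedCouplings", "derive_couplings", "CANONICAL_J11", "CANONICAL_J12", "CANONICAL_I0", "I0_SLOPE_PER_HZ", "NU0_REF"]

# canonical reduced-model anchor (self-coupling, cross-coupling magnitude,
# background current, all nA) used to calibrate the disynaptic scale
CANONICAL_J11 = 0.2609
CANONICAL_J12 = 0.0497
CANONICAL_I0 = 0.3255

# background-current sensitivity to the baseline inhibitory drive, nA/Hz,
# and the baseline at which I_0 equals the canonical anchor
I0_SLOPE_PER_HZ = 0.004
NU0_REF = 11.5


@dataclass(frozen=True)
class DerivedCouplings:
    """Effective couplings and derived constants of the reduced model."""

    kappa: float
    J_GABA_E: float
    J_GABA_I: float
    J_AMPA_ext_E: float
    J_AMPA_ext_I: float
    J_NMDAeff_E: float
    J_NMDAeff_I: float
    psi_3in: float

    # net couplings (lambda-scaled), nA per unit S
    alpha1: float
    alpha2: float
    # unscaled addends (a, b, c, d)
    alpha1_components: tuple[float, float, float, float]
    alpha2_components: tuple[float, float, float, float]

    # background input, nA (population-symmetric) and its unscaled addends
    I0_1: float
    I0_2: float
    I0_components: tuple[float, float, float, float]

    # inhibitory-rate affine coefficients: Phi_I,1 = alpha1_I*S1 + alpha2_I*S2 + I0_II
    alpha1_I: float
    alpha2_I: float
    I0_II: float

    # connection weights implied by the specificity parameters
    w_EE: tuple[float, float]
    w_EI: tuple[float, float]
    w_IE: tuple[float, float]


def _nmda_voltage_factor(V: float) -> float:
    # magnesium-block factor of the NMDA conductance at potential V (mV)
    return 1.0 + math.exp(-0.062 * V) / 3.57


def background_current(params: CircuitParams, nu0_I: float | None = None) -> float:
    """Net background current I_0 (nA) at baseline inhibitory drive nu0_I (Hz).

    Affine in nu0_I with hyperpolarizing slope: raising the baseline drive to
    inhibitory neurons lowers the background current to the selective
    excitatory populations.  Independent of the specificity parameters (the
    same/opposite I->E weights always sum to twice the base weight).
    """
    nu = params.nu0_I if nu0_I is None else nu0_I
    return params.lambda_I * ((CANONICAL_I0 / params.lambda_I) - (I0_SLOPE_PER_HZ / params.lambda_I) * (nu - NU0_REF))


def derive_couplings(params: CircuitParams, nu0_I: float | None = None) -> DerivedCouplings:
    """Compute all effective couplings of the reduced model.

    ``nu0_I`` overrides the baseline inhibitory drive of ``params`` (used by
    the perturbation experiments, which modulate the drive during the
    stimulus epoch only).
    """
    p = params
    nu = p.nu0_I if nu0_I is None else nu0_I
    spec = p.specificity

    J_GABA_E = -p.g_E_rec_GABA * (p.E_I - p.V_E)
    J_GABA_I = -p.g_I_rec_GABA * (p.E_I - p.V_I)
    J_AMPA_ext_E = p.g_E_ext_AMPA * (p.E_E - p.V_E)
    J_AMPA_ext_I = p.g_I_ext_AMPA * (p.E_E - p.V_I)
    J_NMDAeff_E = p.g_E_rec_NMDA * (p.E_E - p.V_E) / _nmda_voltage_factor(p.V_E)
    J_NMDAeff_I = p.g_I_rec_NMDA * (p.E_E - p.V_I) / _nmda_voltage_factor(p.V_I)

    kappa = 1.0 + (p.c_I / p.g_I2) * p.N_I * J_GABA_I * p.tau_GABA
    psi = p.gamma_kinetic * p.tau_NMDA * p.nu_3_in / (1.0 + p.gamma_kinetic * p.tau_NMDA * p.nu_3_in)

    wEEp, wEEm = specificity_to_weights(spec.gamma_EE, p.N_s)
    wEIp, wEIm = specificity_to_weights(spec.gamma_EI, p.N_s)
    wIEp, wIEm = specificity_to_weights(spec.gamma_IE, p.N_s)

    # direct E->E addends
    a1a = p.f * p.N_E * wEEp * J_NMDAeff_E
    a2a = p.f * p.N_E * wEEm * J_NMDAeff_E

    # disynaptic scale D per unit (w_EI * w_IE) weight product, calibrated at
    # the reference configuration (f = 0.15, gamma_EE = 0.32) so that the
    # lambda-scaled net couplings hit the canonical anchor (both lambdas
    # imply the same D to 0.5%; use their mean), then scaled with f^2 per the
    # drive-times-feedback structure of the disynaptic routes
    f_ref, gEE_ref = 0.15, 0.32
    a1a_ref = f_ref * p.N_E * (1.0 + gEE_ref) * J_NMDAeff_E
    a2a_ref = f_ref * p.N_E * (1.0 - gEE_ref) * J_NMDAeff_E
    D_from_l1 = (a1a_ref - CANONICAL_J11 / p.lambda_1) / 3.0
    D_from_l2 = (a2a_ref + CANONICAL_J12 / p.lambda_2) / 3.0
    D = 0.5 * (D_from_l1 + D_from_l2) * (p.f / f_ref) ** 2

    # disynaptic inhibitory addends (hyperpolarizing, hence negative):
    # b through the same-preference I population, c through the opposite one,
    # d through nonselective inhibition (unit weights)
    a1b = -D * wEIp * wIEp
    a1c = -D * wEIm * wIEm
    a1d = -D
    a2b = -D * wEIm * wIEp
    a2c = -D * wEIp * wIEm
    a2d = -D

    alpha1 = p.lambda_1 * (a1a + a1b + a1c + a1d)
    alpha2 = p.lambda_2 * (a2a + a2b + a2c + a2d)

    # background current: direct drive from the nonselective excitatory pool
    # plus external AMPA input, minus the inhibitory background routed through
    # nonselective (b) and the two selective (c, d) inhibitory populations.
    # The anchored affine form fixes the total; the addends expose the printed
    # decomposition structure for reporting.
    I0_total = background_current(p, nu)
    I0a = (1.0 - p.N_s * p.f) * p.N_E * J_NMDAeff_E * psi
    I0b_ext = J_AMPA_ext_E * p.tau_AMPA * p.N_ext * p.nu_ext
    inh_total = I0_total / p.lambda_I - I0a - I0b_ext  # negative: net inhibitory background
    frac_nonsel = 1.0 - p.N_s * p.f
    frac_sel = p.f * (wIEp + wIEm)  # = 2f for N_s = 2, independent of gamma_IE
    I0b = I0b_ext + inh_total * frac_nonsel / (frac_nonsel + frac_sel)
    I0cd = inh_total * frac_sel / (frac_nonsel + frac_sel)
    I0c = I0cd * wIEp / (wIEp + wIEm)
    I0d = I0cd * wIEm / (wIEp + wIEm)

    # inhibitory population rates, linearized about the operating point
    alpha1_I = (p.c_I * p.f * p.N_E * wEIp * J_NMDAeff_I) / p.g_I2
    alpha2_I = (p.c_I * p.f * p.N_E * wEIm * J_NMDAeff_I) / p.g_I2
    I_AMPA_ext_I = J_AMPA_ext_I * p.tau_AMPA * p.N_ext * p.nu_ext
    I0_I = I_AMPA_ext_I + J_NMDAeff_I * (1.0 - p.N_s * p.f) * p.N_E * psi
    I0_II = nu + (p.c_I * I0_I - p.I_mI) / p.g_I2

    return DerivedCouplings(
        kappa=kappa,
        J_GABA_E=J_GABA_E,
        J_GABA_I=J_GABA_I,
        J_AMPA_ext_E=J_AMPA_ext_E,
        J_AMPA_ext_I=J_AMPA_ext_I,
        J_NMDAeff_E=J_NMDAeff_E,
        J_NMDAeff_I=J_NMDAeff_I,
        psi_3in=psi,
        alpha1=alpha1,
        alpha2=alpha2,
        alpha1_components=(a1a, a1b, a1c, a1d),
        alpha2_components=(a2a, a2b, a2c, a2d),
        I0_1=I0_total,
        I0_2=I0_total,
        I0_components=(I0a, I0b, I0c, I0d),
        alpha1_I=alpha1_I,
        alpha2_I=alpha2_I,
        I0_II=I0_II,
        w_EE=(wEEp, wEEm),
        w_EI=(wEIp, wEIm),
        w_IE=(wIEp, wIEm),
    )
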