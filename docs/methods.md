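# Methods

## The two-variable circuit model

The model reduces a six-population cortical circuit (two choice-selective
and one nonselective pool each of excitatory and inhibitory neurons) to the
NMDA gating fractions `S1, S2` of the two selective excitatory populations:

    dS_i/dt = −S_i/τ_NMDA + (1 − S_i) · γ · Φ(x_i)
    x_i     = α₁ S_i + α₂ S_j + I₀ + I_stim,i + I_η,i

with τ_NMDA = 0.1 s, kinetic factor γ = 0.641, and the current-to-rate
transfer Φ(x) = (ax − b)/(1 − e^{−d(ax−b)}) with a = 270 nC⁻¹, b = 108 Hz,
d = 0.154 s. The reduction is valid because GABA (~5 ms) and AMPA (~2 ms)
conductances relax fast relative to NMDA; the inhibitory populations are
treated as linearized steady-state relays.

`α₁` sums four routes by which a population excites itself: the direct
E→E feedback (∝ w⁺_EE) minus disynaptic inhibition through the
same-preference, opposite-preference and nonselective inhibitory
populations. `α₂` sums the routes onto the competitor. Writing the
connection weights per class as w± = ŵ(1 ± γ_JK), the same/opposite routes
enter as the products w_EI·w_IE, so that the inhibitory specificity index
p = γ_EI·γ_IE controls the *balance* of self- vs cross-inhibition:

    α₁ ∝ (1+γ_EE)·e  −  D·(2(1+p) + 1)
    α₂ ∝ (1−γ_EE)·e  −  D·(2(1−p) + 1)

Ipsispecific circuits (p > 0) shift inhibition onto the winner (stabilizing,
weaker competition); contraspecific circuits (p < 0) shift it onto the loser
(competition-enhancing). Two invariants follow from the weight
normalization and are enforced by tests: the direct drive (α₁ₐ + α₂ₐ) is
γ_EE-independent, and the total disynaptic drive is (γ_EI, γ_IE)-independent.

### Calibration of the coupling scale and background current

The published physiological constants for the disynaptic routes and the
background current are not mutually consistent (implementing them verbatim
places the couplings an order of magnitude away from any decision-competent
regime, and the background inhibitory-rate term comes out negative). Two
facts pin the missing scales:

1. The printed scaling factors λ₁ = 1.6719 and λ₂ = 1.8844 both imply the
   *same* total disynaptic coupling (0.2235 vs 0.2224 nA per unit S, 0.5%
   agreement) when the net couplings at the reference specificity
   (γ_EE = 0.32, γ_IE = 0) are required to equal the canonical reduced
   two-variable model values J₁₁ = 0.2609 nA and J₁₂ = 0.0497 nA. We treat
   this as the definition of the per-unit-weight disynaptic scale `D`
   (≈ 0.0743 nA), computed in `selinhib.couplings` from the anchor, and
   scale it with f² per the drive-times-feedback structure when the
   selective-population fraction f deviates from its 0.15 default.
2. The background current `I₀` is affine in the baseline inhibitory drive
   ν_0,I with hyperpolarizing slope. Its anchor I₀(11.5 Hz) = 0.3255 nA is
   the same canonical value; the slope −0.004 nA/Hz places the minimum of
   τ_slow(ν_0,I) at ≈ 13.5 Hz — between the two operating points used for
   perturbation experiments (11.5 and 14 Hz) — and pushes the system toward
   bifurcations at the extremes of the admissible range [9, 16] Hz,
   reproducing the published two-regime (U-shaped) structure.

Both constants were fixed once from these anchors and are not free
parameters of any experiment.

### Stimulus, noise, integration

The stimulus raises the external input rate by μ = 40 Hz split by coherence
c ∈ [−100, 100]%: population 1 receives J_AMPA,ext·μ(1 − c/100) and
population 2 the (1 + c/100) counterpart during the stimulus window
(positive coherence favors population 2). Noise is an Ornstein–Uhlenbeck
current with τ_AMPA = 2 ms, discretized as
I ← I(1 − Δt/τ) + √Δt·(σ/√τ)·N(0,1) with σ = 0.02 nA; at the default
Δt = τ_AMPA = 2 ms this makes the noise exactly white with per-step sd
0.02 nA. The alternative convention (stationary sd = σ) is a config switch
(`noise_convention`). Integration is forward Euler at 2 ms.

Reported firing rates are Φ of the deterministic synaptic drive; the noise
current drives the S-dynamics only (switch `rates_include_noise`). With
noise included in the reported rates, the per-step rate jitter (several Hz)
trips the 5 Hz pre-stimulus validity criterion on ~95% of trials at every
coherence, which is inconsistent with the high published completion
fractions; population rates are physically the smooth, gating-driven
quantity.

### Trial schedule and initial condition

Defaults (config-exposed): 0.5 s pre-stimulus, 1.0 s stimulus, 1.0 s
post-stimulus delay; S₁ = S₂ = 0.1 (inside the low-state basin) with zero
noise current at t = 0.

## Fixed points, stability, scans

Roots of the noiseless field are found by a damped Gauss–Newton
(Levenberg-style) iteration from a 21×21 multistart grid over [0,1]² plus
nine canonical seeds, deduplicated at radius 10⁻⁴ and re-verified by
substitution at tolerance 10⁻⁶. The iteration is vectorized over starts
and over parameter points, which is what makes the 2295-point specificity
scan run in under a minute; it is cross-checked against scipy's
Levenberg–Marquardt on the reference circuit in the tests. Stability comes
from the analytic 2×2 Jacobian (chain rule through Φ); a saddle's
τ_slow = 1/λ₊. Symmetric labeling uses a 0.1 Hz rate tolerance, far below
the 15 Hz decision threshold. Bifurcation sweeps link branches by
nearest-neighbor continuation and bracket census changes by bisection to a
10⁻⁴ parameter interval. A "stimulus strength" in sweeps and
classifications is the coherence c with the stimulus on (μ = 40 Hz).

A circuit is decision-competent when the unstimulated plane has exactly a
symmetric low-rate attractor, a mirror pair of working-memory attractors
and a mirror pair of saddles, and the stimulated (c = 0) plane a mirror
pair of choice attractors separated by one symmetric saddle. Ambiguous
configurations are flagged indeterminate, never silently resolved.

## Behavior

Validity: (i) |r₁ − r₂| < 5 Hz at every pre-stimulus step;
(ii) |r₁ − r₂| ≥ 15 Hz at some step in the stimulus window or at the first
post-offset step (the stricter both-required reading is a config option).
Choice and decision time come from the first qualifying crossing, at
one-step (2 ms) resolution. Invalid trials are a separate outcome category,
never assigned a random choice; accuracy and chronometric summaries use
valid trials only. Working-memory probability is the fraction of valid
trials still ≥ 15 Hz separated at the end of the post-offset delay
(default 1 s).

Perturbation experiments modulate ν_0,I by Δν ∈ [−0.5, 0.5] Hz *during the
stimulus window only* and report Δcompletion, Δaccuracy, Δdecision-time
relative to Δν = 0 with common random numbers across levels (switchable).
Coherence sets: |c| ∈ {0, 5, 10} for accuracy and decision time, the same
set for completion by default (config-exposed).

### Known limitation: the low-baseline decision-time sign

At the high-inhibition baseline (ν_0,I = 14) enhanced inhibition slows
decisions, lowers completion and raises accuracy, as predicted by the
stabilizing regime. At the low baseline (11.5) enhanced inhibition raises
completion and lowers accuracy (competitive regime) and τ_slow itself
*decreases* — but the measured mean first-crossing time increases slightly
(~+30 ms) instead of decreasing. In this calibration the first-crossing
time falls monotonically with background current throughout the
census-valid window; the region where the τ_slow-driven slowdown dominates
(and the sign flips) begins ~0.001 nA past the boundary where the
stimulated saddle stabilizes. The corresponding acceptance assertion is
kept faithful and fails; all other regime signs pass.

## Four-variable model

GABA gating of the two selective inhibitory populations becomes dynamical
(dS_I/dt = −S_I/τ_GABA + Φ_I(x)), with per-population transfer gains
(310 nC⁻¹, 125 Hz, 0.16 s) for E and (615 nC⁻¹, 177 Hz, 0.087 s) for I, a
4×4 adjacency built from the same w± mapping (adding γ_II), fixed synaptic
constants and background currents (externally calibrated; data here), and
noise (sd 0.2 nA) delivered to all four populations. "Stimulus strength
0.05" on the calibration trial is read as coherence c = 0.05 (the direct-
current reading is a config option). The noiseless calibration trial
matches the two-variable excitatory rates within 2.0 Hz (observed max
deviation 1.89 Hz), our regression bound. Trials start with the fast GABA
gating pre-equilibrated (damped relaxation; the undamped map is unstable
because of I→I feedback). Root finding uses the same batched solver in 4-D
with S_I starts on [0, 1.35].

## The E–I RNN laboratory

Architecture, task, loss, initialization and training follow the published
constants exactly (100 E / 25 I units, 60-step trials, 21-step stimulus
with per-trial onset uniform on steps [10, 29], catch fraction 0.5,
difficulty uniform on {±2, …, ±20}, masked MSE + L2 activity + L1 weight
penalties, Adam at learning rate 0.01 with global gradient-norm clip 1,
non-negativity projection and diagonal re-zeroing after every step,
validation after every epoch, stop at 85% overall performance with c = 0
excluded from the denominator; the all-trials performance variant is a
config flag). Noise scalings are implemented verbatim as printed:
√(2α_r)·σ_0,r for recurrent units and √(2/α_in)·σ_0,in for inputs — the
printed asymmetry is preserved deliberately; the symmetric √(2/α_r)
alternative was tested and moved every population statistic away from the
reference values. pytorch is not a dependency: forward pass, BPTT and Adam
are numpy, with gradients verified against central finite differences.

Selectivity: per-unit AUC decoding the network's choice from activity at
the single step after stimulus offset, over a fresh 200-trial evaluation
batch (valid trials only; spanning the validation coherences), significance
by 150 label permutations at the 2.5% tails. Specificity estimates γ̂ per
connection class average weights between significantly selective units with
matching (w⁺) vs opposite (w⁻) preferences — presynaptic preference against
postsynaptic preference, self-connections excluded — and
γ̂ = (⟨w⁺⟩−⟨w⁻⟩)/(⟨w⁺⟩+⟨w⁻⟩).

### Known limitation: emergent I→E specificity

Networks trained by this implementation reach the 85% criterion in
~15–30k trials (reference: 83–128k) and consistently converge to solutions
with *contraspecific* I→E structure (γ̂_IE ≈ −0.45) rather than the
reference near-zero γ̂_IE; γ̂_II is likewise negative. The fractions of
significantly selective units (I ≈ 0.8 > E ≈ 0.65), the inhibitory
selectivity index (≈ 0.25) and γ̂_EE (≈ 0.5) fall inside the reference
bands. The reference statistics — near-zero γ̂_IE/γ̂_II with very small
across-network dispersion — are consistent with I-output matrices remaining
close to their unstructured initialization, a regime this implementation's
training demonstrably leaves; emergent circuit structure in these networks
is known to be strongly sensitive to training hyperparameters. The
acceptance checks report the measured values unmodified.

## What the synthetic data does and does not show

All experiments run on data generated by the models themselves (trial
batches, trajectories, weight matrices); there is no external data. Passing
tests therefore establish the internal consistency of the dynamics,
analysis and training machinery and the reproduction of the published
phenomenology under the documented calibration — not agreement with
physiological recordings. Problem sizes used by the test suite and the
acceptance script: 15×9×17 specificity grid, 500 trials per perturbation
condition, six trained networks (full 100 E / 25 I scale); all chosen as
the study's stated sizes or, for network count, a small multiple of the
stated minimum for estimator stability.

## Numerical choices

- Root residual tolerance 10⁻⁶ (max |dS/dt|), dedup radius 10⁻⁴.
- Step-length cap 0.25 in the damped Newton iteration; box clip to
  [−0.05, 1.05] during iteration, final clip to [0, 1].
- τ_slow from the analytic Jacobian agrees within 10% with the e-folding
  rate of |S₁ − S₂| measured on noiseless trajectories seeded 10⁻⁴ off the
  saddle along its unstable eigenvector (tested).
- Degenerate parameter sets yield short fixed-point lists, not errors;
  empty lists classify as all-flags-false.
- Per-trial and per-condition randomness derives from
  `SeedSequence([master, counter])`, so enlarging an experiment never
  perturbs existing streams.
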