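# Methods

## Model and assumptions

The synapse is bipartite: the synaptic cleft is treated as a lossless
channel, so the current leaving the pre-synaptic bouton is the current
entering the post-synaptic dendrite, and the entire retrograde-messenger
concentration produced post-synaptically reaches the pre-synaptic receptors.
The messenger is lipid-derived (2-AG-like) and produced on demand, so no
vesicle-depletion dynamics are modeled on the feedback path. Plasticity is
carried by a single scalar weight ω whose growth rate (the synaptic
efficacy) is the product of release probability and the spike-activity and
neurotransmitter traces; ω has no decay term, so it is non-decreasing under
non-negative drive — runs probe the build-up of potentiation, not its
reversal.

Two realizations of the same synapse are maintained deliberately:

- the **reference engine** integrates the full nonlinear equations with an
  adaptive Runge–Kutta method (rtol 1e-8, atol 1e-11 by default), applying
  spike jumps at exact event times and feeding the messenger back without
  delay — the mathematical ideal;
- the **discretized engine** advances all states by forward Euler at a fixed
  step δ on the linearized equations, with binary spike binning `u[n]`, a
  messenger delay line of `feedback_delay_steps` cycles (default 25), ω
  pinned to 0 at start with the first `warmup_samples` flagged for rejection
  (values are stored untouched; only the mask marks them), and optional
  binary32 quantization of every state store. Forward Euler is the scheme a
  one-update-per-clock datapath realizes; higher-order schemes belong to the
  reference engine only.

A sample stored at time t is the pre-jump (left-limit) state in both
engines, so a spike in `[nδ, (n+1)δ)` first influences sample n+1; with
grid-aligned stimuli the two engines are jump-for-jump comparable and the
remaining discrepancy is the integration scheme plus the linearization.

## Linearization choices

- **Inhibition probability.** The linearized mode uses the rectangular
  hyperbola `−7e-5/(Inh − 1e-5) + 1.1`. The exact-mode curve is the
  double-exponential sigmoid `exp(exp(−s/(g·Inh))) − 1` with the printed
  scale `s = 1e-7`; `g` (`inh_operating_gain`, default 8.8414e-4) is the
  configurable adjustment of the inhibitory-complex equilibrium point. Its
  default is calibrated analytically so the exact curve is *tangent* to the
  hyperbola (equal value and slope) at the default operating concentration
  `Inh = 1.433e-4`: tangency makes the two curves agree to first order
  across the whole operating band, so the inhibitory-complex ripple around
  the operating point injects no first-order error into the weight. Both raw curves leave [0, 1] outside
  the operating region and are clamped; the engine counts clamp events.
- **Mediator gate.** The tanh gate is replaced by the cubic `1 + ks − ks³`
  as printed, with ks clipped to ±1.5 (clips counted) and the polynomial
  floored at 0. The printed cubic is not monotone — strong drive closes the
  gate and large negative ks opens it — so the linearized mediator should be
  read as a hardware-faithful surrogate, not a biophysical improvement; the
  canonical third-order tanh series (`sm_poly="canonical"`) is available and
  is the variant that obeys the next-Taylor-term error bound.
- **Mitochondrial series.** The exchanger release term uses
  `m(1 − m + m²)`, the actual series of `m/(1+m)`; the printed series form
  drops the leading factor of m, which would remove the rest fixed point
  (release would be positive at m = 0), so the leading factor is restored.
- **Membrane surrogate.** The cubic `V − V³/3` is replaced by
  `f̂(V) = V(1 − |V|/2)` (odd, fixed point at 0, one absolute value and one
  multiply; it matches the cubic exactly at 0 and ±1.5 and deviates at most
  1/6 in between). The verbatim non-odd form `1 − |V|/2` is available as
  `fhn_surrogate="printed"`.
- **Messenger output.** The third-order series of `exp(−k₂·Cc^k₁)` as
  printed; exact mode uses the untruncated exponential. The printed curve is
  decreasing in calcium; a direction flag (`rm_decreasing`) exposes the
  biologically increasing alternative without changing the default.

## Parameter registry

No complete table of time constants and control parameters accompanies the
source model; the registry below was chosen once, before any acceptance
measurement, to satisfy the stated design conditions — the sub/supra-
threshold mediator switch is exercised by the canonical stimulus, calcium
stays where `k₂·Cc^k₁ ≤ 1`, the inhibitory complex sits at the tangency
point of the two inhibition curves, and a healthy three-unit chain
propagates spikes end to end. All values are config keys; none is buried in
code.

| parameter | default | note |
|---|---|---|
| τ_r, τ_inh, τ_c, τ_d | 0.1, 1.0, 0.1, 0.1 s | trace time constants; τ_inh ≫ spike period smooths Inh |
| τ_syn | 0.05 s | alpha-kernel; pulses at 10 Hz partially fuse |
| P_init | 0.5 | low-pass glutamatergic release probability |
| RM_rest | 1e-4 | canonical drive leaves RMtrace just above it |
| RM drive | 1.433e-3 | puts the Inh equilibrium at the tangency point 1.433e-4 |
| τ_cc, τ_ce, τ_sm | 1.0, 1.0, 0.5 s | calcium/mediator timescales |
| c1..c4, r, α, β, k_mito | 1, 1, 0.05, 0.1, 0.1, 0.05, 0.5, 0.05 | keep Cc ~ O(0.1–1) |
| v1max, v2max, Kd, K_Na, Na | 0.5, 0.2, 1, 1, 1 | mitochondrial exchange |
| S_Sm, I_Sm, d_Sm | 4.0, 0.05, 0.5 | gate gain/threshold/decay |
| Ipost, τ_v, τ_w | 1.05, 0.01, 0.04 s | membrane quiescent below drive, oscillatory above Isyn ≈ 0.05; τ_v = τ_w = 1 recovers the dimensionless printed form |
| δ | 1e-4 s | fixed step; chosen so Euler error on the fastest trace meets the <1% fidelity design rule |
| feedback delay | 25 steps | clock-cycle equivalent of the feedback latency |
| warm-up | 0.031 s / δ samples | initialization latency window |

The printed membrane equations carry unit (dimensionless) time constants;
with the synaptic kernel in seconds that would make the membrane two orders
of magnitude slower than its drive and no chain would propagate. τ_v and
τ_w are therefore explicit parameters — a units choice, with the
dimensionless form one setting away.

## Scenario layer

Every noise source is seeded, attached to the mechanism's noise-carrying
parameter, and passes through at least one dt-integration before touching a
trace (FXS and D-cycloserine integrate a noisy parameter into a current;
TSC integrates noise into the receptor-rate ODE; Shank and chromosome-15
random-walk their gain parameter). Scenario modifications act on the current
entering the post-synaptic region; the pre-synaptic weight loop sees the
unmodified current. Mechanisms with neutral parameters and zero noise are
skipped entirely, so the healthy run is reproduced bit-for-bit.

The TSC receptor-rate construct `dk/dt = +k ∓ k_nam/pam` is an unstable
linear growth; trajectories saturate at 0.25×–4× of the base rate (events
counted). Its ratio ρ to baseline scales the mediator activation threshold
(coupling 1.0) and the output/mediator gain (coupling 0.25). Under NAM,
ρ falls: the threshold drops faster than the amplitude, which yields the
more-activations / lower-peak phenotype structurally (an early design used
a hard amplitude ceiling instead, but a ceiling flattens the output into a
plateau and erases the very activation events the phenotype is about).
Under PAM, ρ rises: higher amplitude, stronger low-pass. The D-cycloserine
channel `dx/dt = (Isyn + x)·k_glut − N(t)·k_dcs + 1/k_adjust` is the only
mechanism whose noise rides an unstable mode (gain e^{k_glut·t}, capped at
|x| ≤ 5), which is why its noise-induced distortion dominates the FXS and
TSC responses at matched noise amplitude.

## Metrics

Relative RMS is shape-sensitive; the Area Average Error (AAE) compares
areas under the curves and ignores latency, which is the biologically
meaningful comparison once RMS error is small (what a synapse conserves is
the transferred quantity). The distortion score is
`1 + 0.5·RMS/100 + 0.25·|gain − 1| + 0.25·excess-spikes` on the synaptic
output potential (the scenario-modified current entering the post-synaptic
region), so the ideal trace scores exactly 1 for any weights.
Supra-threshold events are local maxima above the effective activation
threshold I_Sm — peak counting stays meaningful when successive pulses fuse
above the threshold, where crossing counting collapses. Type A/B/C
boundaries default to 1.5 and 3.0 on the normalized score; the source
classification is visual, so these are documented tuning constants and only
the ordering/boundary semantics are asserted by tests.

## Network estimator

Units are chained by thresholding the membrane potential (upward crossings
of 1.0, two-sample refractory). Coordination is judged per unit against the
all-healthy chain by a coincidence F-score (one-to-one spike matching
within 20 ms); the network fails when the worst unit's disagreement exceeds
0.5. Timing, not rate, carries the criterion: an oscillating membrane keeps
its firing rate while completely losing its lock to the input, so
rate-based criteria are blind to exactly the noise-induced decoherence the
scenarios produce (both a rate-deviation and a smoothed-rate-correlation
criterion remain available as pluggable alternatives). Affected-unit
selection and per-unit scenario noise use independently derived sub-seeds.
`min_failure_fraction` scans the fraction grid, averaging the failure
indicator over seeds; a fraction fails when the mean indicator exceeds 0.5.
No reference values exist for these fractions; the outputs are exploratory
and validated by their stated properties (healthy chains never fail; the
indicator is monotone in the affected fraction for high-noise scenarios).

## What the synthetic stimuli do and do not show

All inputs are generated internally: periodic or homogeneous-Poisson spike
trains and zero-mean Gaussian (optionally uniform) noise series. They
emulate paced afferent drive and molecular parameter noise; they do not
emulate correlated/colored noise, bursting statistics, or stimulus
estimation from recordings. Passing tests therefore demonstrate internal
consistency of the model and its discretization, and qualitative phenotype
orderings under the stated noise convention — not quantitative agreement
with electrophysiological recordings.

## Numerical choices and degenerate inputs

Problem sizes: the canonical fidelity run uses a 10 s horizon at δ = 1e-4
(1e5 steps); scenario comparisons use 6 s at δ = 2e-4; network sweeps use
6–8 s at δ = 5e-4 with 3-unit chains and 5 seeds per fraction. The Euler
convergence study uses δ ∈ {8, 4, 2, 1}×1e-4 with the discretized engine
switched to the exact equations (`equations="exact"`), because Euler on the
*linearized* equations converges to the continuous linearized model, and
the δ-independent linearization offset would mask the scheme's first-order
slope. Division by calcium in the ER equation is guarded by a 1e-6 floor
(reference mode only; the linearized mode holds Ce ≡ 0). Runs start at the
stabilized operating point (`init="equilibrium"`: drive-consistent trace
levels, mediator/calcium/mitochondria at their quiescent fixed point, ω = 0
always); `init="rest"` zeroes the traces instead. Two spikes landing in one
δ-bin count once (binary u[n]; occurrences logged). Probability clamps,
gate clips, scenario caps and quantization overflows are counted and
reported in the trace metadata; single-precision overflow aborts the run
naming the step and variable.

## Known limitations

- ω never decays, so long runs saturate the mediator gate (ks clipping
  becomes permanent at high drive); horizons are chosen within the
  pre-saturation regime.
- The linearized mediator gate inherits the printed cubic's non-monotonicity
  (see above); cross-mode mediator comparisons carry a configured bound of
  0.4 relative RMS rather than a series-remainder bound.
- The messenger feedback loop saturates inhibition at RM ≈ 1 with the
  default registry (release probability → 0), which is why the canonical
  protocol uses the constant-drive configuration; feedback-mode studies
  need a steepened RM(Cc) curve (larger k₂).
- Scenario support in the reference engine is limited to the healthy model;
  the synaptopathy layer is defined per clock step on the discretized engine.
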