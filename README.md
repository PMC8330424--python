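# synapsim

Simulation of a glutamatergic synapse with retrograde-messenger-mediated
plasticity (RMMP), built for two audiences: computational neuroscientists who
want a compact, fully specified bipartite synapse model with an autism-
spectrum synaptopathy layer, and hardware/algorithm co-designers who need a
software twin of a fixed-step, linearized datapath realization of the same
equations, with quantitative error analysis between the two.

## The model

**Pre-synaptic bouton** (Tsodyks–Markram-style traces). The messenger uptake
trace, inhibitory complex, spike-activity trace and neurotransmitter trace
follow

```
dRMtrace/dt = −RMtrace/τ_r + RM          dInh/dt = −Inh/τ_inh + RMtrace·C
dC/dt       = −C/τ_c   (+Δ per spike)    dD/dt   = −D/τ_d    (+1 per spike)
```

where Δ is the anti-symmetric Hebbian increment (+1 when pre and post are
co-active, −1 when either is active alone; post-activity is the indicator
RMtrace > RM_rest). Release probability is `P_rel = P_init·(1 − P_inh(Inh))`
with `P_init = 0.5` — the low-pass glutamatergic regime; release
probabilities below 0.3 make a synapse a high-pass filter, above 0.7 a
low-pass filter, intermediate ones band-pass (`metrics.filter_class`). The
synaptic weight grows as `dω/dt = P_rel·C·D` (its rate is the synaptic
efficacy) and the transmitted current is an alpha-function superposition,
realized either in closed form or as the coupled linear pair
`dY/dt = (Z−Y)/τ`, `dZ/dt = −Z/τ + u[n]`, with `Isyn = ω·Y`.

**Post-synaptic dendrite.** Cytoplasmic calcium `Cc` exchanges with the ER
store `Ce` through a two-variable flux `f(Cc, Ce)`, receives external influx
`r + α(W − W_rest) + β·Sm` and a mitochondrial term `k·dm/dt`; the IP3-like
secondary mediator `Sm` is gated by `1 + tanh(S_Sm(Isyn − I_Sm))`; the
membrane is a FitzHugh–Nagumo pair; and the retrograde messenger output is
`RM(Cc) = exp(−k₂·Cc^k₁)` (k₁ = 2.0447, k₂ = 9.1799e-12), clamped to [0, 1].

**Two engines.** `simulate_reference` integrates the full nonlinear
equations adaptively (scipy `solve_ivp`) with spike jumps at exact event
times. `simulate_discretized` is a forward-Euler loop at fixed step δ on the
linearized equations (rectangular-hyperbola inhibition probability,
truncated-series mitochondrial and messenger terms, cubic-polynomial tanh
gate, piecewise-linear membrane), with spike binning to `u[n]`, a 25-cycle
messenger feedback delay line, warm-up flagging (ω pinned to 0 at start) and
optional IEEE-754 binary32 quantization of every state store — the software
twin of a one-update-per-clock pipeline.

**Synaptopathy scenarios.** Five composable perturbations with seeded noise:
FXS (FMRP-loss influx accumulator), TSC under negative/positive allosteric
modulation of mGluR5 (threshold/gain coupling through an unstable
receptor-rate construct), D-cycloserine/NMDAR competition (an unstable
competitive current channel — the model's strongest noise amplifier),
Shank/Neuroglin current scaling with an NMDAR weight-stage gain, and
chromosome-15 inhibition of mediator production. Distortion against the
ideal run is scored on the synaptic output potential (normalized so the
ideal run scores exactly 1) and classified into Types A/B/C.

**Networks.** Feed-forward chains of units (membrane threshold crossings
become the next unit's spike train) with a seeded affected subset;
`min_failure_fraction` estimates the smallest fraction of dysfunctional
units that breaks pre/post coordination (per-unit spike-train coincidence
against the all-healthy chain).

## Worked example

```python
from synapsim import RunConfig, rms_error

cfg = RunConfig()                      # canonical run: 10 Hz input, 10 s,
disc = cfg.run("discretized")          # constant RM drive just above the
ref = cfg.run("reference")             # plasticity threshold
m = ~disc.warmup_mask                  # drop the 0.031 s warm-up window
print(f"relative RMS: {rms_error(disc.output()[m], ref.output()[m]):.3f} %")
print(f"final synaptic weight: {disc.series['omega'][-1]:.3f}")
```

prints

```
relative RMS: 0.107 %
final synaptic weight: 2.306
```

meaning the fixed-step linearized engine reproduces the continuous-time
reference synaptic output potential to ~0.1% relative RMS — within the <1%
fidelity the datapath design targets — while the synaptic weight grows to
2.31 over ten seconds of paired activity.

The same protocols are available from the shell:

```
synapsim compare -o out/            # reference vs discretized fidelity
synapsim scenario -c fxs.yaml -o out/   # ASD scenario vs ideal distortion
synapsim sweep-delta -o sweep.json  # step-size error sweep
synapsim network -o net.json        # failure-fraction sweep
```

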