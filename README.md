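# twocpt — soma–axon coupling and neural coincidence detection

`twocpt` simulates and analyzes a family of two-compartment
conductance-based neuron models of auditory coincidence detectors such as
the principal cells of the medial superior olive (MSO), which compare the
arrival times of inputs from the two ears with sub-millisecond precision.
It is a library for computational neuroscientists who want to ask how the
electrical coupling between a neuron's input region (soma and dendrites)
and its spike generator (axon initial segment) shapes temporal processing,
without committing to a detailed morphological reconstruction.

## The model

The neuron is reduced to two compartments: Cpt1 (soma, capacitance c₁,
leak g₁) receives synaptic current, and Cpt2 (axon, c₂, g₂) carries the
spike-generating sodium current, connected by an axial conductance g_c:

    c₁ V₁′ = −g₁(V₁ − E_lk) − g_c(V₁ − V₂) − I_KLT,1 − I_syn + I_app
    c₂ V₂′ = −g₂(V₂ − E_lk) − g_c(V₂ − V₁) − I_KLT,2 − I_Na

Instead of picking the five passive parameters by hand, the family is
indexed by two voltage-attenuation factors — forward coupling
κ₁→₂ = g_c/(g₂+g_c) (soma→axon) and backward coupling κ₂→₁ = g_c/(g₁+g_c)
(axon→soma). Given the measured somatic properties of gerbil MSO neurons
(R_in = 8.5 MΩ, τ_exp = 0.34 ms, V_rest = −58 mV) and a small axon/soma
area ratio α = 0.01, every coupling pair (κ₁→₂, κ₂→₁) maps to a unique
conductance set

    g_c = κ₂→₁ / (R_in (1 − κ₁→₂ κ₂→₁)),   g₁ = g_c(1/κ₂→₁ − 1),
    g₂ = g_c(1/κ₁→₂ − 1),   c₁ = τ_exp/R_in,   c₂ = α c₁,

that leaves the passive dynamics of the soma invariant across the whole
family — so any difference in spiking behaviour is attributable to the
coupling configuration alone. Spikes come from a reduced sodium current
I_Na = g_Na m∞³(V₂) h (V₂ − E_Na) with instantaneous activation and
dynamic inactivation h; a low-threshold potassium (KLT) current can be
allocated to either compartment, frozen (acting as leak) or voltage-gated.

On top of the simulator (a compiled exponential-Euler integrator with a
variable-step stiff solver as cross-check), the package implements the
standard measurement battery for this preparation:

* **gNa_ref** — smallest g_Na at which two simultaneous unitary EPSGs
  evoke a spike; the anchor for all g_Na sweeps.
* **Coincidence sensitivity** — maximum firing-rate difference between
  coincident and non-coincident phase-locked afferent input over a g_Na
  sweep (an ROC-style hit/false-alarm analysis).
* **Tonic/phasic classification** and the repetitive-firing boundary
  gNa_tonic for current steps.
* **Slope sensitivity** (Δg_Na) from threshold conductances for slow vs
  fast current ramps.
* **Refractory period** from paired strong EPSGs.
* **V₂–h phase-plane tools**: nullclines, left knees, fixed points.

## Worked example

```python
from twocpt import MSO_SPEC, WEAKLY_COUPLED, FORWARD_COUPLED
from twocpt.protocols import find_gna_ref, refractory_period

for name, cc in [("weak", WEAKLY_COUPLED), ("forward", FORWARD_COUPLED)]:
    gref = find_gna_ref(MSO_SPEC, cc)
    rp = refractory_period(MSO_SPEC, cc, gna_ref_value=gref)
    print(f"{name:<8} gNa_ref = {gref:6.0f} nS   refractory = {rp.value:.2f} ms")
```

prints

```
weak     gNa_ref =   6284 nS   refractory = 0.92 ms
forward  gNa_ref =    398 nS   refractory = 0.72 ms
```

The weakly coupled model (κ₁→₂ = 0.3, κ₂→₁ = 0.2) needs ~16× more sodium
conductance to reach spike threshold than the forward-coupled model
(κ₁→₂ = 0.8, κ₂→₁ = 0.2), because synaptic depolarization attenuates on
its way to the spike generator; and it recovers more slowly between
inputs. Both effects favour the forward-coupled configuration as a
high-frequency coincidence detector. The `examples/` directory walks
through each capability (`python examples/01_model_family.py`, …) with a
few lines of printed output per script.

A thin CLI mirrors the protocols:

```bash
twocpt gnaref --kf 0.8 --kb 0.2
twocpt refractory --kf 0.3 --kb 0.2
twocpt sweep --protocol slope --out slope.csv
```

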