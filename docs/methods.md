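# Methods

## Model

The neuron is a two-compartment conductance-based model. Compartment 1
(soma and dendrites) integrates synaptic and injected current; compartment
2 (axon initial segment) generates spikes:

    c₁ V₁′ = −g₁(V₁ − E_lk) − g_c(V₁ − V₂) − I_KLT,1 − I_syn + I_app
    c₂ V₂′ = −g₂(V₂ − E_lk) − g_c(V₂ − V₁) − I_KLT,2 − I_Na

Units are mV, ms, nS, pA, pF throughout (nS·mV = pA, pF·mV/ms = pA);
input resistance is accepted in MΩ and converted once at the construction
boundary (1/MΩ = 1000 nS). Synaptic current is I_syn = g_syn(t)(V₁ −
E_syn) with E_syn = 0 mV, so it depolarizes from rest; injected current
I_app enters with a positive sign so positive steps depolarize.

### Coupling parameterization

The family of models is indexed by the forward and backward attenuation
factors κ₁→₂ = g_c/(g₂+g_c) and κ₂→₁ = g_c/(g₁+g_c). Inverting these
together with the somatic constraints (R_in, τ_exp, E_lk, area ratio
α = A₂/A₁) gives the closed-form construction in
`params.build_two_compartment_params`. Consequences used as test oracles:

* the steady-state input resistance at Cpt1 equals R_in exactly, for every
  coupling pair (2×2 linear solve);
* c₁ = τ_exp/R_in exactly (40 pF at the defaults), independent of coupling;
* the ratio of compartment time constants is τ₂/τ₁ = α·κ₁→₂/κ₂→₁, so with
  α = 0.01 and the restriction κ₁→₂/κ₂→₁ ≤ 10 the axon is always at least
  an order of magnitude faster than the soma. This timescale separation is
  what makes the soma's passive response invariant (to O(τ₂/τ₁)) across
  the family.

Only the wedge κ₁→₂ ≥ κ₂→₁ is admitted (voltage propagates forward with
less attenuation than backward, as observed in MSO cells). The default
sweep grid is κ ∈ {0.1, 0.15, …, 0.9} on both axes (step 0.05),
triangularized by the two constraints; the grid spacing is a resolution
choice, not a model parameter.

The specific capacitance is taken as C_m = 0.9 μF/cm², which together
with c₁ = 40 pF implies a soma area of 4444 μm². Areas are bookkeeping
only; the dynamics use c₁ and c₂ directly.

### Channels

Kinetics follow the Rothman–Manis lineage of auditory-brainstem models,
temperature-scaled to 35 °C (factors 0.24 on τ_h, 0.46 on τ_w):

* Sodium: I_Na = g_Na m∞³(V₂) h (V₂ − E_Na), E_Na = +55 mV, with
  instantaneous activation m∞(V) = [1 + exp(−(V+38)/7)]⁻¹ and dynamic
  inactivation h (h∞ midpoint −65 mV, slope 6 mV, falling).
* KLT: I_KLT = g_KLT w⁴ z∞(V_rest) (V − E_K), E_K = −106 mV. The slow
  inactivation gate z is always frozen at its resting value. The
  activation curve is implemented as the rising Boltzmann
  w∞(V) = [1 + exp(−(V+65)/6)]⁻¹: an activation gate must open with
  depolarization for KLT to act as negative feedback, so the falling
  orientation of the same midpoint/slope (which would describe an
  inactivation gate) is rejected. Sodium activation midpoint/slope are
  exposed as module constants so alternative calibrations can be swapped
  in one place; with the defaults above, the measured reference
  conductances of the three named models (6284, 398, 2007 nS) agree with
  the published in-vitro-constrained values to a few tenths of a percent,
  which we take as confirmation of the calibration.

Both active currents carry constant rest-correction terms so that they
vanish exactly at V_rest; rest is then an exact equilibrium of the full
system (verified to machine precision), and adding channels never moves
the resting potential.

KLT allocation replaces a fraction (default 10%) of a compartment's leak
with KLT conductance while preserving the total resting conductance
exactly: g_leak,new = (1−f)·g_lk and g_KLT = f·g_lk/[w∞⁴(V_rest)
z∞(V_rest)]. In frozen mode the result is dynamically identical to the
passive model; in dynamic mode w evolves.

## Stimuli

* Unitary EPSG: g_syn(t) = 125.25(e^(−t/0.18) − e^(−t/0.10)) nS, causal,
  peaking at 26.70 nS 0.132 ms after onset; its amplitude makes a single
  event depolarize the soma by ≈6 mV. Event trains superpose linearly and
  scale multiplicatively (scale 2 ≡ two simultaneous unitary inputs).
* Current steps (amplitude, onset, duration) and ramps (slope to a
  2500 pA plateau) for the firing-pattern and slope protocols.
* Phase-locked afferent trains: five independent fibers per ear, each an
  inhomogeneous point process with von Mises rate
  r(t) ∝ exp(κ_v cos(2πft − φ)), normalized to 200 spikes/s per fiber,
  generated by Lewis thinning and pruned by a 0.75 ms absolute refractory
  gap. The concentration κ_v is chosen per frequency to hit vector-strength
  targets {0.80, 0.75, 0.70, 0.65, 0.60, 0.55} at 200–700 Hz
  (interpolated in between), emulating the degradation of auditory-nerve
  phase locking with frequency. The driving rate is inflated by the
  dead-time factor 1/(1 − r·τ_ref) so the realized rate approximates the
  target. The second ear is delayed by 0 (coincident), half a stimulus
  period (anti-phase) or 0.5 ms (fixed-delay mode).

This generator is a synthetic stand-in for a full auditory-periphery
model: it reproduces the statistical structure the coincidence analysis
depends on — independent fibers, periodic rate modulation whose locking
degrades with frequency, refractoriness — but none of the cochlear
filtering, level dependence, adaptation, or across-fiber rate
heterogeneity of the real periphery. Absolute firing-rate differences
therefore depend on these declared parameters, and the package treats
only orderings and qualitative trends across coupling configurations as
meaningful for the stochastic protocols; the deterministic protocols
(thresholds, refractory periods, phase-plane quantities) do not involve
the generator at all.

Seeding: a master seed spawns per-fiber and per-trial substreams through
`numpy.random.SeedSequence`, so any trial is reproducible in isolation
and results are independent of evaluation order.

## Numerics

The system is stiff: with c₂ = 0.4 pF and thousands of nS of open sodium
conductance the axon's effective time constant drops below 0.1 μs during
the spike upstroke. The default integrator advances each state variable
by its exact exponential relaxation toward the instantaneous steady state
computed from the start-of-step values of the other variables
(exponential Euler), which is unconditionally stable for the stiff decay.
Synaptic conductance is carried by two auxiliary exactly-decaying states,
with event deposits weighted by the exact fractional decay from event
time to the step boundary, so the conductance waveform has no grid error.

Step sizes: 0.1 μs (`DEFAULT_DT`) for deterministic threshold searches —
at this step, halving the step moves spike times by well under 1 μs on
the paired-EPSG protocol, and threshold conductances are converged to
≲0.2% — and 1 μs (`RATE_DT`) for the long stochastic firing-rate runs and
step-response classification, where only spike counts matter. A
variable-step stiff solver (LSODA, rtol 1e-6, atol 1e-8 by default)
provides an independent cross-check and is held to agreement with the
compiled engine in the test suite. Output is sampled at 10 μs.

Spikes are upward crossings of V₂ = −20 mV separated by ≥0.5 ms, with
linearly interpolated crossing times. The threshold separates spikes from
subthreshold activity in all coupling regimes because V₂ spike peaks
range from ≈0 mV (strong forward coupling) to ≈+40 mV (weak coupling);
both threshold and dead time are configurable.

## Protocols and their conventions

* **gNa_ref**: geometric bisection on g_Na for one spike to a
  simultaneous pair of unitary EPSGs (scale 2 at t = 5 ms), bracket width
  0.5%; ±2% around the returned value flips the outcome (validated in
  tests).
* **Coincidence sensitivity**: g_Na sweep 0.2–2.2 × gNa_ref in steps of
  0.05; firing rate = spike count / 250 ms; mean ± SE over 100 trials
  (SE = sample SD/√n). Sensitivity is the maximum of (coincident −
  non-coincident) rate over the sweep; the maximizing g_Na is reported as
  the best operating point. Reduced problem sizes (25 trials, 9 sweep
  points) are used in the test suite; SE scaling with trial count is
  itself tested.
* **Firing-pattern classification**: 200 ms step; quiescent = no spikes;
  tonic = ≥5 spikes with the last in the final third of the step; phasic
  = anything else with ≥1 spike (onset-confined firing; the 25 ms onset
  window and the spike-count minimum are declared constants). The tonic
  boundary gNa_tonic is the smallest g_Na giving a tonic label at any
  amplitude on a 41-point geometric grid spanning 100–10 000 pA, located
  by an ascending scan and bisection (2% bracket). This simulation-based
  classification replaces continuation-based bifurcation analysis; the
  tonic region closes at high g_Na via depolarization block, which is why
  the search scans upward rather than assuming monotonicity.
* **Slope sensitivity**: threshold g_Na (bisection as above) for ramps of
  500 and 1000 pA/ms to a 2500 pA plateau; Δg_Na = thr(500)/thr(1000) ≥ 1.
* **Refractory period**: paired EPSGs, each 3× unitary. "Both events
  fire" requires one spike in [t₁, t₂) and one at/after t₂, with the
  control that a single event at the same g_Na evokes exactly one spike —
  without the control, conductances high enough to fire doublets to one
  event would spuriously count. The delay-threshold curve reports the
  smallest such g_Na on a 41-point geometric grid spanning 0.2–4 ×
  gNa_ref per delay; the refractory period is the smallest delay (bisected
  to 0.01 ms) at which a threshold exists within that sweep. At a fixed
  g_Na (e.g. exactly gNa_ref) the same predicate yields the longer
  per-conductance recovery delay; both measures are exposed, and the
  bounded sweep range is part of the measure's definition.
* **Phase plane**: the V₂-nullcline is solved for h in closed form (h is
  linear in the V₂ equation), sampled at 0.05 mV on [−80, 60] mV with the
  singular point V₂ = E_Na excluded and h clipped to [−0.1, 1.1] for
  plotting; every retained point balances the V₂ equation to <1e−8 pA.
  Knees are discrete local maxima refined by a quadratic fit; fixed points
  are sign-change-bracketed roots of h_null(V₂) − h∞(V₂) polished by
  Brent's method. When axonal KLT is dynamic its activation enters the
  nullcline at quasi-steady state w = w∞(V₂) — an approximation used only
  for these diagnostics, never by the simulator. A clamped-V₁ simulation
  mode ties the phase-plane picture to dynamics (middle-branch fixed
  point ⇔ repetitive firing of the clamped fast subsystem).

## Design choices where the design was open

* The restriction diagnostics use the time-constant ratio τ₂/τ₁ =
  α·κ₁→₂/κ₂→₁ as the small parameter; it is self-consistent with the
  constructed parameters (tested) and with the ≤10·α bound.
* The printed specific capacitance is interpreted as 0.9 μF/cm² — the
  only unit for which 40 pF, 4444 μm² and the capacitance density are
  mutually consistent.
* Injected current and synaptic current enter the soma equation with
  opposite sign conventions (see Model); a single signed "input current"
  cannot serve both the conductance-based synapse and depolarizing
  current steps.
* The refractory-period sweep cap (4 × gNa_ref) is a declared part of the
  measure: beyond it the threshold curve is not scientifically meaningful
  because responses stop being attributable to individual events.

## Limitations

* Two compartments only: no dendritic cable, no multi-node axon, no
  inhibition, no I_h current; KLT inactivation is frozen.
* Temperature (35 °C) is baked into the gating constants.
* The afferent generator is statistical, not mechanistic (see Stimuli);
  stochastic-protocol outputs are comparative, not absolute predictions.
* The tonic boundary is resolved to the amplitude grid and a 2% g_Na
  bracket; boundaries of genuinely subcritical bifurcations could be
  missed between grid points.
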