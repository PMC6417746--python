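"""Refractory period from paired strong synaptic events.

Two EPSGs, each three times the unitary amplitude, are delivered with a
varying delay. The refractory period is the smallest delay at which both
events can evoke spikes for some sodium conductance within the standard
sweep (0.2-4 x gNa_ref). Strong forward plus weak backward coupling
recovers fastest, which is what lets that configuration follow
high-frequency coincident inputs.
"""

from twocpt import MSO_SPEC, WEAKLY_COUPLED, FORWARD_COUPLED, STRONGLY_COUPLED
from twocpt.protocols import delay_threshold_curve, find_gna_ref, refractory_period

models = [("weak", WEAKLY_COUPLED), ("forward", FORWARD_COUPLED), ("strong", STRONGLY_COUPLED)]

for name, cc in models:
    gref = find_gna_ref(MSO_SPEC, cc)
    rp = refractory_period(MSO_SPEC, cc, gna_ref_value=gref)
    rp_ref = refractory_period(MSO_SPEC, cc, gna=gref, gna_ref_value=gref)
    print(f"{name:<10} refractory = {rp.value:.2f} ms "
          f"(at fixed gNa = gNa_ref: {rp_ref.value:.2f} ms)")

print("\nthreshold gNa (x gNa_ref) vs delay, forward-coupled model:")
curve = delay_threshold_curve(MSO_SPEC, FORWARD_COUPLED, delays=(0.8, 1.0, 1.5, 2.0, 2.5))
for _, row in curve.iterrows():
    print(f"  delay {row.delay_ms:.2f} ms -> threshold {row.threshold_gna_mult:.2f} x gNa_ref")
print("\nLonger recovery delays never require more sodium conductance.")
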