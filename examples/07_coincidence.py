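"""Coincidence-detection sensitivity from phase-locked afferent input.

Each 'ear' drives five phase-locked afferent fibers; coincident trials
align the two ears, non-coincident trials delay one ear by half the tone
period. Sweeping gNa (in multiples of gNa_ref) traces an ROC-like curve;
sensitivity is the maximum firing-rate difference. A reduced sweep (10
trials, 5 gNa values) keeps this demo quick -- expect a few minutes.
"""

import numpy as np

from twocpt import MSO_SPEC, WEAKLY_COUPLED, FORWARD_COUPLED
from twocpt.protocols import coincidence_sensitivity

sweep = tuple(np.round(np.arange(0.2, 2.21, 0.5), 10))
for name, cc in [("weak", WEAKLY_COUPLED), ("forward", FORWARD_COUPLED)]:
    res = coincidence_sensitivity(
        MSO_SPEC, cc, freq=500.0, noncoincident_mode="antiphase",
        gna_sweep=sweep, n_trials=10, seed=1,
    )
    print(f"{name:<10} max rate difference = {res.value:.0f} +- {res.se:.0f} sp/s "
          f"at gNa = {res.extras['best_gna_mult']:.2f} x gNa_ref "
          f"(hit {res.extras['rate_coinc']:.0f}, false-alarm {res.extras['rate_noncoinc']:.0f})")

print("\nThe forward-coupled model separates coincident from non-coincident")
print("input more cleanly: a higher hit rate at a comparable false-alarm rate.")
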