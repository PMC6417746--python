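"""Reference sodium conductance (gNa_ref) of the named models.

gNa_ref is the smallest sodium conductance at which a pair of
simultaneous unitary EPSGs evokes a spike. It anchors every gNa sweep:
models whose absolute excitability differs by an order of magnitude are
compared at matched multiples of their own gNa_ref.
"""

from twocpt import MSO_SPEC, WEAKLY_COUPLED, FORWARD_COUPLED, STRONGLY_COUPLED
from twocpt.protocols import KltSettings, find_gna_ref

models = [("weak", WEAKLY_COUPLED), ("forward", FORWARD_COUPLED), ("strong", STRONGLY_COUPLED)]
dyn = KltSettings("cpt2", 0.1, "dynamic")

print(f"{'model':<10}{'gNa_ref (nS)':>14}{'with dynamic KLT in axon':>26}")
for name, cc in models:
    g_frozen = find_gna_ref(MSO_SPEC, cc)
    g_dyn = find_gna_ref(MSO_SPEC, cc, dyn)
    print(f"{name:<10}{g_frozen:>14.0f}{g_dyn:>18.0f}  (+{100 * (g_dyn / g_frozen - 1):.0f}%)")

print("\nWeak coupling demands ~16x more sodium conductance than the forward-")
print("coupled configuration to reach spike threshold from the same input;")
print("dynamic KLT opposes depolarization and raises the threshold by 5-30%.")
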