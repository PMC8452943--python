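"""The two-attribute worked item: reduced-pattern probabilities <-> deltas.

An item requiring two attributes has four reduced patterns.  Its printed
success probabilities 0.30 / 0.70 / 0.42 / 0.93 decompose uniquely (the
identity-link map is an invertible linear system) into an intercept 0.30,
main effects 0.40 and 0.12, and an interaction effect 0.11 — mastering both
attributes adds more than the sum of the separate main effects.
"""

import numpy as np

import cdmkit as ck

probs = [0.30, 0.70, 0.42, 0.93]  # patterns (0,0), (1,0), (0,1), (1,1)
delta = ck.delta_from_probabilities(probs)
print("probabilities:", probs)
print("delta (intercept, main A, main B, interaction):", np.round(delta, 2))

for reduced in [(0, 0), (1, 0), (0, 1), (1, 1)]:
    p = ck.gdina_probability(delta, reduced)
    print(f"  P{reduced} = {p:.2f}")

print("\nFor a single-attribute item, P(0) and P(1) are the guessing and "
      "1-slipping parameters:")
print("  g =", ck.dina_probability(0.28, 0.16, (0,)),
      " 1-s =", ck.dina_probability(0.28, 0.16, (1,)))
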