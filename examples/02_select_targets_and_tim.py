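"""Select a minimal relevant target set and build the Target Inhibition Map.

A 10-drug screen over 6 kinases is generated from a hidden rule (the
tumor dies iff K0 and K2 are both inhibited, or K4 alone is).  Floating
forward search finds the smallest target set whose induced drug bins
explain the scores; the TIM then predicts every inhibition combination.
"""

import numpy as np

from timkit import BinarizedDrug, build_tim, sffs_select

hidden = lambda bits: int((bits[0] and bits[2]) or bits[4])
profiles = [
    [1, 0, 1, 0, 0, 0],  # hits K0+K2 together: sensitive
    [1, 0, 0, 0, 0, 0],  # K0 alone: not enough
    [0, 0, 1, 1, 0, 0],  # K2 plus an irrelevant kinase: not enough
    [0, 0, 0, 0, 1, 0],  # K4 alone suffices
    [0, 1, 0, 0, 0, 0],
    [1, 0, 1, 0, 0, 1],
    [0, 0, 0, 1, 0, 0],
    [0, 0, 1, 0, 1, 0],
    [1, 1, 0, 0, 0, 0],
    [0, 0, 0, 0, 0, 1],
]
drugs = [
    BinarizedDrug(f"d{i}", dtip=np.array(bits, dtype=np.uint8), score=float(hidden(bits)))
    for i, bits in enumerate(profiles)
]

tset = sffs_select(drugs)
print(f"selected targets: {tset.members}  (set score Gamma = {tset.score:.3f})")

tim = build_tim(drugs, tset)
print("\ncombination -> predicted sensitivity")
for pattern in range(2**tim.n):
    hits = ", ".join(f"K{tim.members[i]}" for i in range(tim.n) if pattern >> i & 1)
    label = "{" + (hits or "none") + "}"
    print(f"  {label:<18} {tim.predict(pattern):.2f}")

print(
    "\nGamma = 0 means the selected kinases explain the screen perfectly; "
    "unmeasured combinations interpolate between their closest measured "
    "subset and superset, so predictions respect 'inhibiting more never hurts'."
)
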