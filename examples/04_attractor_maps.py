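"""Attractor strength over the stimulus plane (peak separation x width).

Repeated stochastic simulations from random initial conditions estimate the
probability of reaching each tuning class per stimulus cell — small
separations integrate (VA), large separations segment, with winner-take-all
favored for narrow inputs and transparency for broad ones.
"""

import numpy as np

from ringmt import (KernelParams, NetworkParams, RingGrid, StimulusSpec,
                    probability_map)

grid = RingGrid(202)
pmap = probability_map(
    ("ps", np.array([40.0, 120.0, 170.0])),
    ("pw", np.array([5.0, 25.0])),
    StimulusSpec(), KernelParams(alpha=0.0, beta=-10.0),
    NetworkParams(noise_eps=0.01), grid, n_trials=20, seed=1, t_max=1500.0)

print("P(label) from 20 random-initialization trials per cell")
print(f"{'PS':>5} {'PW':>5} {'VA':>6} {'WTA/SB':>7} {'TP':>6}")
for i, ps in enumerate(pmap.axis1):
    for j, pw in enumerate(pmap.axis2):
        print(f"{ps:5.0f} {pw:5.0f} {pmap.probs['VA'][i, j]:6.2f} "
              f"{pmap.probs['WTA_SB'][i, j]:7.2f} "
              f"{pmap.probs['TP'][i, j]:6.2f}")
print("\nVA wins at PS=40 regardless of width; at PS=170 the narrow input")
print("(PW=5) selects a winner in most trials while the broad one favors")
print("transparency — the attractor-strength structure of the model.")
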