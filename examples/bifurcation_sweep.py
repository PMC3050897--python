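"""Recall as a bifurcation: sweep the input strength up and down.

With frozen weights, the input strength gamma is a bifurcation
parameter: below a critical value gamma* the network stays in a
spontaneous attractor; above it, a fixed point whose output matches
the learned target is reached.  Because attractors coexist over an
interval of gamma, the up-continued and down-continued sweeps can
disagree — hysteresis.
"""

import numpy as np

from arpnet import (
    NetworkParams,
    generate_onehot_curriculum,
    run_curriculum,
    sweep_input_strength,
)

params = NetworkParams()
cur = generate_onehot_curriculum(params.N, 9, seed=0)
result = run_curriculum(params, cur, seed=0, keep_traces=False)
w = result.weight_history[-1]
k = int(np.argmax(result.fractions[-1]))  # a well-memorized mapping
grid = np.linspace(0.0, 4.0, 17)

for mode in ("continued_up", "continued_down"):
    br = sweep_input_strength(w, cur[k].input, cur[k].target, params, grid,
                              mode=mode, seed=1)
    marks = "".join("#" if m else "." for m in br.matched)
    print(f"{mode:15s} gamma in [0, 4]: {marks}  gamma* = {br.gamma_star}")
# '#' marks grid points where the reached attractor is a fixed point
# matching the target.  A mismatch between the two rows over some
# gamma interval is the coexistence (hysteresis) window.
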