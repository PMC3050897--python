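"""Learning overlapping inputs with bounded synapses.

Three mappings over two input neurons — (1,0), (0,1) and (1,1) — map
to one-hot targets over three output neurons.  Because the third input
contains both others, unbounded weights cannot separate the codes; a
finite upper bound w_max plus a rehearsal schedule (consolidate the
disjoint mappings, then graft the overlapping one in short bursts,
stopping as soon as all three recall simultaneously) solves the task.
"""

import numpy as np

from arpnet.overlap_task import overlap_params, run_overlap_task

result = run_overlap_task(seed=8, params=overlap_params(n_hidden=6, w_max=1.0))

print(f"presentations used: {result.n_steps}")
for mapping, frac in zip(result.curriculum, result.recall):
    print(f"  input {mapping.input.astype(int)} -> target "
          f"{mapping.target.astype(int)}: recall fraction {frac:.2f}")
print(f"all three mappings recalled simultaneously: {result.all_recalled}")
# A recall fraction is the share of 40 random initial states from which
# the clamped input drives the output to within eps_d of its target.
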