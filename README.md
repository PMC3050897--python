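# arpnet

Sequential learning in a three-layer firing-rate network with
error-gated Hebbian/anti-Hebbian plasticity on two synaptic timescales,
and the dynamical-systems analyses that go with it: memory-capacity
measurement, censuses of the spontaneous attractors that learning
shapes (fixed points, limit cycles, itinerancy over stored patterns),
and recall treated as a bifurcation of the attractor landscape under
increasing input strength.

The package is for computational neuroscientists studying how
reinforcement-style learning rules sculpt autonomous neural dynamics —
in particular the view that a memory is not an attractor reached *from*
an input-as-initial-state, but a bifurcation: the input, applied as a
bias of strength γ, destabilizes the spontaneous attractor and creates
a fixed point expressing the stored output.

## Model

Input, hidden and output layers of rate neurons; the input layer is
clamped at `γ·ξ`. Hidden and output rates relax as

```
τ dx_i/dt = −x_i + f(I_i),     f(u) = 1 / (1 + exp(−β(u − θ)))
```

with excitatory forward synapses `J_ih` (input→hidden), `J_ho`
(hidden→output), excitatory backward synapses `J_oh` (output→hidden),
and fixed mutual inhibition `c_inh Σ_{j≠i} x_j` inside each layer
(winner-take-all, sparse activity). Learning follows the associative
reward-penalty scheme: a single scalar error `d = ‖x_out − T‖/‖T‖`
gates every synapse,

```
dJ[post,pre]/dt = (λ(δ)/τ_syn) · δ · (x_post − r0) · x_pre ,   δ = +1 if d < ε_d else −1
```

Hebbian (`δ=+1`) stabilization consolidates the pattern that matches
the target; anti-Hebbian (`δ=−1`) search destabilizes everything else,
so the activity itinerates until it finds the target. Forward synapses
use the slow timescale `τ_F`, backward synapses the faster `τ_B`;
sequential memory works when `τ ≪ τ_B ≪ τ_F`. Penalty updates run at a
reduced rate `λ ≤ 1` (the classic reward-penalty asymmetry), which
protects consolidated memories from being spent by later searches.

## Worked example

`examples/learn_single_mapping.py` learns one one-hot association from
zero synapses and recall-tests it:

```
$ python examples/learn_single_mapping.py
input neuron 2 -> target neuron 2
step succeeded: True after 13781 tau (96% of recorded time in search)
recall fraction from random states: 1.00 -> memorized: True
```

The long duration is the search phase: starting from zero weights, the
anti-Hebbian rule must first grow enough forward drive for any output
neuron to ignite, then rotate through candidate outputs until the
target wins, at which point `d < ε_d` flips the rule to Hebbian and
the association consolidates. The recall fraction is the share of 20
random initial states from which the clamped input drives the output
to within `ε_d` of the target — 1.00 means the evoked fixed point's
basin covers essentially the whole state space.

The other example scripts each demonstrate one analysis:
`capacity_curve.py` (capacity peaks at the intermediate backward
timescale), `spontaneous_itinerancy.py` (input-free trajectories visit
the learned targets; attractor census), `bifurcation_sweep.py`
(recall threshold γ* and hysteresis between up/down sweeps),
`overlap_task.py` (the bounded-weight task with overlapping inputs).
A thin CLI mirrors these: `arpnet learn|capacity|attractors|bifurcate|
phase2d|overlap-task|make-curriculum` (see `--help`;
`examples/reference_config.toml` documents every configuration key).

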