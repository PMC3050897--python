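# Methods

## Model

`arpnet` simulates a three-layer firing-rate network. An input layer of
`N_in` binary units is clamped at `gamma * xi` (a boundary condition, never
integrated). Hidden and output layers of `N` rate-coding neurons each obey

    tau dx_i/dt = -x_i + f(I_i),      f(u) = 1 / (1 + exp(-beta (u - theta)))

with currents

    I_i^hidden = gamma * sum_j J_ih[i,j] xi_j + sum_j J_oh[i,j] x^out_j
                 + c_inh * sum_{j != i} x^hid_j
    I_i^out    = sum_j J_ho[i,j] x^hid_j + c_inh * sum_{j != i} x^out_j

Three plastic, excitatory (nonnegative) weight matrices connect the layers:
forward `J_ih` (input→hidden) and `J_ho` (hidden→output), and backward
`J_oh` (output→hidden). Intralayer inhibition is a fixed scalar `c_inh`
with no self-connections; it implements winner-take-all competition, so
activity in each layer is sparse (one or few active units).

## Plasticity: the associative reward-penalty rule

One scalar error is shared by all synapses: the normalized distance
`d = |x_out - T| / |T|` between the output rates and the current binary
target. Its comparison against the threshold `eps_d` sets the reward sign
`delta` (+1 when `d < eps_d`, else −1), and every plastic weight evolves as

    dJ[post,pre]/dt = (lambda(delta) / tau_syn) * delta * (x_post - r0) * x_pre

clipped to `[0, w_max]`, with `tau_syn = tau_f` for both forward matrices
and `tau_b` for the backward matrix. For the input→hidden matrix the
presynaptic rate is the clamped input-layer value `gamma * xi_j`, so
synapses from silent inputs never change. `delta = +1` is Hebbian —
co-active pairs strengthen and the ongoing pattern is stabilized; `delta =
−1` is anti-Hebbian — the active pattern is destabilized while
below-baseline units (postsynaptic rate under the spontaneous rate `r0`)
are gently potentiated, which is what drives the itinerant search and,
from zero weights, bootstraps the first association.

`lambda(delta)` is the reward-penalty learning-rate asymmetry of the
classic associative reward-penalty algorithm: 1 for reward, `lambda_penalty
<= 1` for penalty. This asymmetry is load-bearing. The search
(anti-Hebbian) phase and the erosion of previously consolidated forward
weights are driven by the same terms; with symmetric rates the erosion per
search is independent of `tau_b` and the capacity peak at the intermediate
backward timescale disappears. With `lambda_penalty = 0.1` the backward
pathway still reconfigures quickly enough to pace the search while the
consolidated forward weights decay an order of magnitude more slowly, and
the capacity ordering tau_b = 10 > tau_b = 100 > tau_b = 1 emerges.

During the stabilization phase the backward matrix is nearly frozen
(`bs_stab_scale = 0.02`): only the forward synapses consolidate the found
association. Fully plastic backward synapses during stabilization build
output→hidden loops of strength ~`0.08 * T_stab / tau_b * tau_b` that
capture every subsequent search and collapse capacity to one or two; a
complete freeze preserves capacity but leaves the learned pairs' backward
loops below the search-built background, so spontaneous orbits match
targets in the output layer only, no limit cycles appear, and the
minimum-distance profile does not improve. The small residual plasticity
is the measured compromise that yields all three phenomena at once.

## Parameters

| name | default | meaning |
|---|---|---|
| `N` | 16 | neurons per layer |
| `tau` | 1.0 | rate relaxation time; the unit of all times |
| `beta` | 100 | activation gain |
| `theta` | `ln(1/r0 − 1)/beta` ≈ 0.022 | activation threshold; anchors `f(0) = r0` |
| `c_inh` | −1.0 | intralayer inhibition |
| `gamma_learn` | 2.0 | input strength while learning and at recall |
| `dt` | 0.01 | explicit-Euler step |
| `r0` | 0.1 | spontaneous rate; plasticity baseline |
| `eps_d` | 0.5 | Hebbian/anti-Hebbian switching threshold |
| `lambda_penalty` | 0.1 | penalty-rate asymmetry |
| `tau_f`, `tau_b` | 100, 10 | forward / backward plasticity timescales |
| `w_max` | ∞ | synaptic bound (finite only for the overlap task) |

The gain matters through the winner-take-all instability condition: the
symmetric equal-activity state of a layer destabilizes only when
`beta * x (1 - x) > 1` at the operating rate. Near the spontaneous rate
this requires `beta > 1 / (r0 (1 - r0)) ≈ 11`, and the ignition threshold
for a fresh output unit falls steeply with `beta`; at `beta = 100`,
learning from zero weights is reliable, while at `beta <= 20` the
network provably deadlocks in a symmetric subthreshold state. `theta` is
tied to `r0` so that an undriven neuron rests at the spontaneous rate,
which is also the baseline of the plasticity rule — the two uses of `r0`
must agree or the search phase stalls.

### Protocol defaults

A learning step succeeds after a contiguous `T_stab = 600 tau` below
`eps_d` and times out at `T_max = 40000 tau`. The long stabilization sets
the forward-weight margin (~`0.007 * T_stab` per co-active pair) that
later searches erode; shorter stabilization (50–300 tau) measurably
halves capacity. The generous timeout covers the first step from zero
weights, whose bootstrap (forward drive must grow before any output can
ignite) takes 12000–40000 tau at the asymmetric penalty rate. Memorization
is tested from `K = 20` random initial states, relaxed for up to 100 tau
with early convergence drop-out; a mapping is memorized when more than
half reach its target within `eps_d`. Capacity experiments that compare
timescale conditions use the same per-step budget (`T_max = 20000`) in
every condition.

## Analysis procedures

**Attractor classification.** After a 200 tau transient a trajectory is a
fixed point if its drift per tau falls below `tol_fp = 1e-6` within the
horizon. Otherwise a 600 tau window is recorded and scanned for returns
to a slow reference point (the recorded frame of minimal speed): the
prominent local minima of the distance to the reference must recur with
consistent spacing (within 20%) at least three times; the spacing is the
period. Trajectories that neither converge nor recur are reported
`unresolved`, never silently dropped. Censuses merge fixed points within
`merge_tol = 0.05` (normalized state distance) and limit cycles with equal
visited-target signatures and periods within 10%.

**Itinerancy.** A visit is a maximal interval during which the output's
normalized overlap with some learned target exceeds 0.9 (an overlap, not
a distance — the natural reading for a threshold of 0.9); simultaneous
matches resolve to the larger overlap, ties to the lower index.

**Minimum-distance profile (D_min).** For each target, the reference is
the converged evoked state (hidden and output concatenated) under its
clamped input. Spontaneous orbits from random initial states are tracked
for the running minimum of `|x - X_ref| / |X_ref|`; the mean over initial
states is reported per target. When profiles at different learning stages
are compared, the references come from the fully trained network of the
lineage — references computed from an early-stage network are meaningless
for not-yet-learned inputs (their evoked state is just the spontaneous
attractor, making the distance trivially zero).

**Bifurcation sweeps.** `independent` mode redraws random initial states
at every grid strength (the superposed-dots diagram); `continued_up/down`
carry the reached state along the grid and expose hysteresis where
attractors coexist. `gamma*` is the smallest grid strength whose reached
attractor is a fixed point within `eps_d` of the target. Saddle-node
points are identified operationally (appearance of the matching stable
fixed point between grid points); a Jacobian eigenvalue check
(`jacobian_eigenvalues`) is provided as a stability validator rather than
a continuation method.

**Overlapping-input task.** Two input neurons, six hidden, three output
neurons, `w_max = 1`. The workable configuration holds the shared output
weight strictly between half the bound and the bound, a band that long
Hebbian phases overshoot; the rehearsal schedule (consolidate the two
disjoint mappings with `T_stab = 300`, then graft the overlapping one in
300 tau bursts with `T_stab = 10`, re-testing all three after every
presentation and stopping at simultaneous recall) reaches the band in
roughly half of random seeds within 200 presentations. The task
demonstrates existence — with bounded weights the overlapping code is
learnable — not a success-rate claim.

## Numerical choices

Explicit Euler with `dt = 0.01 tau` integrates all dynamics; the update is
a convex combination of the current rate and an activation value, so rates
remain in (0, 1) for any `dt <= tau`. Accuracy against an adaptive RK45
reference is first-order in `dt` (verified in the test suite on a small
network). The coupled learning loop and all batched relaxations are
numba-compiled; a pure-Python fallback with identical semantics is used if
numba is unavailable. All randomness flows through seeded
`numpy.random.Generator` instances; every experiment is reproducible from
its seed, and trajectories are bitwise repeatable on one platform.
Relabeling neurons commutes with simulation up to floating-point summation
order; near winner-take-all decision boundaries that roundoff can select a
different winner, which is a property of the dynamics (sensitive
dependence), not of the implementation.

## What the synthetic curricula do and do not show

Inputs and targets are seeded random one-hot bijections — the sparse
coding the model is built for. Results on these curricula probe the
mechanisms (timescale separation, itinerant search, bifurcation recall)
under the cleanest conditions; they do not speak to correlated or graded
patterns, noisy rates, or layer sizes beyond the small networks studied
(N = 8–16 by default; larger sweeps are supported but slow). Known
limitations: spontaneous limit cycles are rare at early learning stages
(about one seed in eight shows one by step nine; they become common
later), the D_min improvement is consistent but small compared with the
figure-level contrast one might expect, and the recency structure of the
slow-backward control's D_min profile is noisy. The discussion-level
biology (neuromodulator interpretation of the reward sign) is out of
scope.
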