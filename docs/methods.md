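# Methods

`emrl` simulates and compares three ways a learner can use episodic memory
in goal-directed spatial navigation: **one-shot learning** (episodic
control: retrieve stored episodes and adopt the best experienced
continuation directly), **replay learning** (train an incremental Q-function
approximator on reactivated stored experiences), and **online learning**
(train on each experience exactly once, no store — a lesion model). The
package generates its own task environments and observations, so every
analysis is a pure function of a configuration and a master seed.

## Task environments

The tunnel-maze family is a topology graph on an integer grid: an open
rectangular chamber (width `5 + 2(l-1)`, height `3 + 2(l-1)` at level
`l = 1..4`) with full 4-neighbour connectivity, and a one-node-wide corridor
("tunnel") that rises `3 + (l-1)` units from the chamber's north-west
corner, runs east over the top and descends on the east side. The agent
starts in the tunnel mouth (the corridor's west foot). The goal is the
corridor's east foot, one unit above the chamber's north-east corner node,
which it also connects to. Two route classes therefore exist:

* the **tunnel route** — long, wall-constrained, easily discovered because
  the corridor funnels a random explorer to the goal;
* the **open route** — strictly shorter, crossing the chamber and entering
  the goal from the node below it, but requiring extensive exploration of
  the open area to discover.

The geometry of the original figure cannot be fully recovered, so the
layout was chosen to realize the reported behavioural signatures: route
funneling through the tunnel, a reward that the one-shot learner never
propagates to the node *below* the goal (it always arrives from inside the
corridor), and per-level growth of +1 tunnel unit north-south and +1/+1/+2
chamber units east/west/south. The builder also accepts explicit layouts
(node list, edges, start, goal, tunnel set) as drop-in replacements, and
validates connectivity, the corridor degree bound and the two-route-class
property on every construction.

The agent's state is a (node, heading) pose with four headings and six
actions: forward/backward along the heading, left/right lateral steps, and
two in-place 90° rotations. Blocked translations are no-ops. Reward is +1
exactly on entering the goal; trials are capped at 600 steps by the runner
(the step function itself is stateless).

## Observations

Agents never see the graph; they see a deterministic per-pose observation
vector (default D = 64) standing in for a camera image. Two properties of
visual input are reproduced: injectivity (distinct poses, distinct views)
and smoothness (nearby poses, similar views). Smoothness is implemented
with random Fourier features over a pose embedding whose spatial part is a
classical MDS embedding of *geodesic* (graph) distances — two positions
separated by a wall look very different to a camera even when their
coordinates are close, so similarity follows traversal distance, not
Euclidean offset. The feature bandwidth is set so that adjacent poses (one
step, or one 90° rotation) correlate at ≈ 0.8; this constant is a modeling
choice (the original study does not characterize view similarity) and is
configurable. With Euclidean-coordinate smoothness instead, value
information generalizes straight through walls and the one-shot agent is
pulled out of the tunnel route it actually learned — an artefact, not a
property of the modelled task.

Episodic control additionally projects observations through a seeded
Gaussian random matrix `phi: x -> Mx` (Johnson–Lindenstrauss distance
preservation is verified in the tests); the projection stage is kept even
at F ≈ D to preserve the algorithm's structure.

## The three learners

All learners act ε-greedily (ε = 0.1) with uniform tie-breaking from a
dedicated seeded stream (ties are common early, when all values are zero),
and discount γ = 0.9.

**Episodic control** keeps a table keyed by the projected observation
(byte-exact keys; the deterministic codec guarantees revisits collide).
At each trial end, every (state, action) of the episode is raised to the
realized discounted return and never lowered, so a single successful trial
installs a complete solution. Acting in a never-visited state averages the
values of the k = 5 nearest stored states (KD-tree, Euclidean metric); a
known state with a missing action defaults to 0 (configurable to skip such
neighbours). Capacity is 50 000 entries with least-recently-updated
eviction; at these problem sizes it never binds. An independent
forward-sweep implementation (scan all stored episodes, accumulate reward
from each occurrence to episode end, take the maximum) is used as an exact
oracle in the tests.

**Replay learning (DQN)** trains an approximator mapping observations to
six action values by squared TD error, with an online and a target
parameter set; targets are `r + γ max_a' Q_target(s', a')`, terminal
transitions use the bare reward, and the target tracks the online
parameters by Polyak averaging with α = 0.01 after every update. As
printed, the published loss omits the discount/terminal mask and the
single-sample loss swaps the two networks; standard Q-learning semantics
are used, and a `printed_form` switch reproduces the literal equations for
reference. The default schedule draws a uniform 32-batch from a 50 000-
capacity FIFO buffer every environment step (Adam, learning rate 1e-4).
Two diagnostic variants cap the data budget at online learning's: batch
size one (one sample per step) and sparse sampling (a 32-batch every 32
steps). Approximators: one-hot tabular, linear, or a two-hidden-layer ReLU
perceptron — all plain numpy with manual gradients; the study-level
default is the linear head on the D = 64 features (the original
convolutional front end is image-specific; the phenomena under study
depend on incremental function approximation, not convolution).

**Online learning** applies the same TD update to each transition exactly
once as it occurs and stores nothing.

## Sequential replay

The biologically motivated sampler reactivates stored experiences one at a
time at trial end. Experiences are deduplicated by (state, action, next
state) with visit counts and reward tallies. The reactivation score of
candidate `e` given the previously reactivated `e'` is

```
R(e|e') = C(e) · D(e|e') · (1 − I(e))
```

* `C(e) = (1 + ln n(e)) · (1 + λ_r · r̄(e))` — saturating familiarity times
  a reward bonus (λ_r = 1). A linear count response is available but, with
  exploration counts spanning 1..several hundred, it drowns the similarity
  factor and no sequential structure can emerge (measured exact-predecessor
  probability mass 0.23 vs 0.51 at β = 5).
* `D(e|e') = exp(−d/σ)` with `d` the pose-graph distance (rotations count
  as steps) between the candidate's *next* state and `e'`'s *current*
  state in reverse mode — chains extend backward along behaviour. σ = 1.
  Node-level anchors make all rotation experiences at a node mutually
  maximally similar, and chains then jitter in place.
* `I(e)` — inhibition: set to 1 on reactivation, decays ×0.9 per step
  (within-event decay; whether the biological inhibition decays within or
  across events is not constrained here). It blocks immediate repeats while
  letting long events revisit experiences.

Sampling follows `p(e|e') ∝ exp(βR) − 1`; the −1 pins never-visited,
just-replayed and unreachable candidates to probability exactly zero. The
β = 0 convention is uniform over eligible experiences — a deliberate
discontinuity from the β → 0⁺ score-proportional limit. Scores are divided
by the maximum strength before sampling, a pure rescaling that calibrates β
so the range {0, 1, 2, 5, 10} spans uniform → near-deterministic reverse
chains regardless of how much history has accumulated. Events are anchored:
the first draw measures similarity to the agent's trial-end pose (replay
initiates where the animal is — at the reward site after a successful
trial). Without the anchor, events begin at merely-popular experiences near
the start and reverse chains propagate nothing (measured: events started a
median of 10 steps from the goal and learning failed entirely).

The random-replay comparator at trial end draws experiences independently
with probability proportional to visit count, in the same event geometry
(N batches × 32, one network update per batch).

## Analyses

* **Learning curves**: per-trial escape latency, mean ± sd across runs;
  learning speed summarized as per-run area under the curve over the first
  100 trials.
* **Test trials**: value-guided rollouts with the behavioural ε = 0.1 kept
  on, 600-step cap, seeded (so labels are reproducible). A purely greedy
  rollout can lock into a two-step argmax cycle of an under-trained value
  function and report a spurious 600-step timeout; the modelled test
  protocol shows such timeouts only for genuinely unlearned (online)
  agents, which the small test-time noise reproduces — shallow cycles
  break, unlearned policies still time out. The rollout primitive accepts
  ε = 0 for deterministic unit-level checks.
* **Solution states**: every state visited during training is tested as a
  start; it is a *solution state* if the greedy agent reaches the goal
  within the cap. Reported: visited fraction, solution fraction and the
  solution-to-visited ratio.
* **Route classification**: a greedy test trajectory is *tunnel* if it
  touches any tunnel-interior node, *timeout* if it hits the cap, else
  *open*.
* **Replay diagnostics**: batch similarity = share of common deduplicated
  experience tuples between two equal-size batches; event similarity =
  mean over unordered batch pairs; aggregated over the first 200 trials.
  Relative performance of sequential over random replay = mean random
  escape latency ÷ mean sequential escape latency (> 1 favours sequential).

## Problem sizes and numerical choices

Simulations in the test suite and acceptance script are sized for a
single-CPU desk run: trend studies (learning-speed ordering, replay
variants) use the level-1 maze with 20 runs × 200 trials and the linear
approximator; asymptotic/propagation checks add level-4 cells; the
route-choice study uses the full protocol (level-4, 50 runs × 500 trials);
the sequential-vs-random comparison uses the tabular head with 10 runs ×
250 trials per cell at 10 replay batches (6 runs at 50 batches). Arithmetic is float64
throughout; exp-overflow in the sampler is avoided by a shifted softmax
once `β·R` exceeds 500 (the −1 terms are negligible there); KD-tree ties
resolve by insertion order; master seeds spawn independent per-run streams
for actions, tie-breaks, initialization and replay.

## Known limitations

Whether sequential replay *outperforms* random replay depends strongly on
the learner it feeds. In the per-sample tabular regime — one Q-learning
update per reactivated experience with live bootstrap — goal-anchored
reverse replay is decisively faster than frequency-weighted random replay
and shows the expected inverse-temperature profile (uniform β = 0 worst
among sequential, intermediate β best); the test suite computes this. Under
the batched protocol, however — one gradient step per 32-tuple batch with
targets from a slowly tracking (α = 0.01) target network — sequence order
within an event cannot propagate value (the bootstrap source is frozen on
the event's timescale), and frequency-weighted random replay, which
approximates on-policy sampling and consolidates the route actually in
use, learns faster at these problem sizes. The suite's
sequential-vs-random comparison reports what this configuration actually
produces rather than a curated subset.

## What the synthetic setting does and does not show

The generator reproduces the *structure* of the original task — topology,
two route classes, sparse terminal reward, four-heading egocentric action
set, deterministic distinctive observations — but not raw-pixel vision,
rendering noise, or image-scale networks. Conclusions supported here are
the comparative properties of the three memory modes and of replay
statistics at matched protocols; absolute latencies and exact percentages
depend on the reconstructed geometry and observation smoothness and should
be read as scaled analogues, not pixel-level replications. Changing goal
locations, eligibility traces, prioritized replay comparisons, and learned
(VAE-style) encoders are out of scope.
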