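# emrl — episodic-memory modes in spatial reinforcement learning

`emrl` is a simulation and analysis package for computational
neuroscientists studying *how* episodic memory drives learning. It
contrasts three ways an agent can use a store of experienced
(state, action, next state, reward) tuples while learning to navigate a
maze to a hidden goal:

* **one-shot learning** — episodic control: a table `Q^EC(s, a)` is updated
  at each trial end to the best discounted return realized from `(s, a)`,
  `Q^EC ← max(R_t, Q^EC)`, so a single successful episode installs a full
  solution; unseen states borrow the mean value of their k = 5 nearest
  stored neighbours in a random-projection space `φ(x) = Mx`;
* **replay learning** — a Q-network trained by gradient descent on the
  squared TD error `(r + γ max_a' Q_w̄(s', a') − Q_w(s, a))²` over
  mini-batches of 32 drawn from the memory store, with a slowly tracking
  target network `w̄ ← w̄ + α(w − w̄)`, α = 0.01;
* **online learning** — the same TD update applied to each experience
  exactly once, with no store (a lesion model of episodic memory).

Beyond uniform replay, the package implements a biologically motivated
sequential replay sampler: at trial end, experiences are reactivated with
probability `p(e|e') ∝ exp(βR) − 1` where the score
`R(e|e') = C(e)·D(e|e')·(1 − I(e))` combines familiarity, similarity to the
previously reactivated experience, and transient inhibition — producing
stochastic *reverse* sequences whose length grows with the inverse
temperature β, for comparison against frequency-weighted random replay.

The environments are parametric "tunnel mazes": an open chamber plus a
longer wall-constrained corridor route to the goal, so that fast and slow
learners systematically discover different route classes. Observations are
deterministic smooth per-pose feature vectors standing in for camera
images. Everything — environments, observations, agents, analyses — is
generated from seeds; there are no external data. See `docs/methods.md`
for the full model description and design rationale.

## Worked example

Train ten one-shot (episodic-control) agents on the smallest maze and
summarize:

```bash
$ emrl run --algo ec --maze 1 --trials 100 --runs 10 --seed 7 --out results/ec1
final mean latency: 10.5 steps
mean test latency: 11.3
route fractions: {'tunnel': 0.1, 'open': 0.9, 'timeout': 0.0}
```

The *final mean latency* is the average number of steps to the goal in the
last training trial (the shortest route takes 6 steps; ε = 0.1 exploration
keeps training latencies slightly above the optimum). The *test latency*
re-runs each trained agent in seeded test trials. The *route
fractions* classify each agent's test trajectory: here 9 of 10
agents found the short route through the open chamber and one kept the
longer corridor ("tunnel") route it discovered first — the signature
sub-optimality of one-shot learning that grows with maze size.

The same study from Python:

```python
from emrl import RunConfig, run_training, learning_curve

config = RunConfig(algorithm="ec", level=1, trials=100, runs=10, master_seed=7)
results = run_training(config)
mean, sd = learning_curve(results)        # per-trial escape latency
```

## Layout

```
src/emrl/maze_env.py            tunnel-maze family, step dynamics, BFS
src/emrl/observation_codec.py   per-pose observations, random projection
src/emrl/experience.py          experience tuples and episode traces
src/emrl/episodic_control.py    one-shot Q table, k-NN lookup, oracle
src/emrl/deep_q.py              approximators, replay buffer, TD updates
src/emrl/sfma_replay.py         sequential replay sampler + random comparator
src/emrl/experiment_metrics.py  training protocol and all analyses
src/emrl/cli.py                 `emrl run / analyze / sweep`
```
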