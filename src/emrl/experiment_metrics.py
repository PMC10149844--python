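"""Training protocol, action selection, and the result analyses.

One *run* trains a single agent for a fixed number of trials from the same
start state; one *study* averages over independent runs.  Everything is a
pure function of the configuration and master seed: the master seed spawns
one stream for the observation codec (the environment's "appearance",
shared by all runs of a study) and independent per-run streams for action
selection, greedy tie-breaks, network initialization and replay sampling.

Analyses mirror the study's result classes: per-trial escape-latency
learning curves with an area-under-curve learning-speed summary, greedy
test-trial latencies, visited/solution-state accounting, tunnel-vs-open
route classification, replay batch similarity and the sequential-vs-random
relative performance ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import deep_q, sfma_replay
from .episodic_control import ECMemory
from .experience import EpisodeTrace, ExperienceTuple
from .maze_env import N_ACTIONS, TopologyMaze, build_tunnel_maze
from .observation_codec import ProjectedCodec, StateEncoder

ALGORITHMS = ("ec", "dqn", "online_dqn")
REPLAY_MODES = ("per_step_random", "trial_end_random", "trial_end_sequential")

DEFAULT_TRIALS = 500
DEFAULT_RUNS = 50
DEFAULT_EPSILON = 0.1
DEFAULT_GAMMA = 0.9
#: trial window of the AUC learning-speed summary
DEFAULT_AUC_WINDOW = 100
#: trial window over which replay-event batch similarity is aggregated
DEFAULT_SIMILARITY_WINDOW = 200


@dataclass(frozen=True)
class RunConfig:
    """Full specification of a training study.

    Defaults follow the study conditions: epsilon-greedy with epsilon=0.1,
    discount gamma=0.9, 500 trials per run, 50 independent runs, 600-step
    trial timeout (owned by the maze), mini-batches of 32.
    """

    algorithm: str = "dqn"
    replay_mode: str = "per_step_random"
    replay_variant: str = "default"  # per-step schedule: see deep_q.update_schedule
    level: int = 1
    trials: int = DEFAULT_TRIALS
    runs: int = DEFAULT_RUNS
    epsilon: float = DEFAULT_EPSILON
    gamma: float = DEFAULT_GAMMA
    beta: float = 5.0
    n_batches: int = 10
    batch_size: int = deep_q.DEFAULT_BATCH_SIZE
    master_seed: int = 0
    approximator: str = "linear"
    learning_rate: float = deep_q.DEFAULT_LEARNING_RATE
    optimizer: str = "adam"
    soft_alpha: float = deep_q.DEFAULT_SOFT_ALPHA
    buffer_capacity: int = deep_q.DEFAULT_BUFFER_CAPACITY
    obs_dim: int = 64
    k_neighbors: int = 5
    ec_capacity: int = 50_000
    sigma: float = sfma_replay.DEFAULT_SIGMA
    lambda_r: float = sfma_replay.DEFAULT_LAMBDA_R
    lambda_i: float = sfma_replay.DEFAULT_LAMBDA_I
    similarity_window: int = DEFAULT_SIMILARITY_WINDOW

    def validate(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.replay_mode not in REPLAY_MODES:
            raise ValueError(f"unknown replay mode {self.replay_mode!r}")
        if self.algorithm != "dqn" and self.replay_mode != "per_step_random":
            raise ValueError(
                f"replay_mode {self.replay_mode!r} only applies to the dqn "
                "algorithm"
            )
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must be in [0, 1]")
        deep_q.update_schedule(self.replay_variant)


@dataclass
class RunResult:
    """Artifacts of one training run."""

    latencies: np.ndarray  # steps to goal per trial (timeout if unsuccessful)
    visited: np.ndarray  # sorted unique visited state indices
    q_table: np.ndarray  # greedy value snapshot over all states, (S, 6)
    replay_diagnostics: dict = field(default_factory=dict)


@dataclass
class SolutionStateReport:
    """Never-visited / visited-non-solution / solution state accounting."""

    never_visited: int
    visited_non_solution: int
    solution: int
    solution_map: np.ndarray  # per-state boolean, True = solution state

    @property
    def total(self) -> int:
        return self.never_visited + self.visited_non_solution + self.solution

    @property
    def visited_count(self) -> int:
        return self.visited_non_solution + self.solution

    @property
    def visited_fraction(self) -> float:
        return self.visited_count / self.total

    @property
    def solution_fraction(self) -> float:
        return self.solution / self.total

    @property
    def solution_to_visited_ratio(self) -> float:
        return self.solution / self.visited_count if self.visited_count else 0.0


# -- action selection -----------------------------------------------------


def epsilon_greedy(
    q_values: np.ndarray,
    epsilon: float,
    rng: np.random.Generator,
    tiebreak_rng: Optional[np.random.Generator] = None,
) -> int:
    """Uniform-random with probability epsilon, otherwise greedy with
    uniform tie-breaking (a dedicated stream keeps tie-breaks reproducible
    independently of the exploration stream)."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must be in [0, 1]")
    if epsilon > 0.0 and rng.random() < epsilon:
        return int(rng.integers(0, len(q_values)))
    return greedy_action(q_values, tiebreak_rng if tiebreak_rng is not None else rng)


def greedy_action(q_values: np.ndarray, rng: np.random.Generator) -> int:
    best = np.flatnonzero(q_values == q_values.max())
    if best.size == 1:
        return int(best[0])
    return int(best[rng.integers(0, best.size)])


# -- training -------------------------------------------------------------


def make_maze(config: RunConfig) -> TopologyMaze:
    return build_tunnel_maze(config.level)


def make_codec(maze: TopologyMaze, config: RunConfig, codec_seed: int) -> ProjectedCodec:
    enc = StateEncoder(maze, dim=config.obs_dim, seed=codec_seed)
    return ProjectedCodec(enc, projection_seed=codec_seed + 1)


def run_training(config: RunConfig) -> list[RunResult]:
    """Execute ``config.runs`` independent runs; reproducible from the
    master seed."""
    config.validate()
    maze = make_maze(config)
    root = np.random.SeedSequence(config.master_seed)
    codec_ss, *run_seeds = root.spawn(config.runs + 1)
    codec_seed = int(codec_ss.generate_state(1)[0] % (2**31))
    codec = make_codec(maze, config, codec_seed)
    return [
        _run_single(config, maze, codec, ss) for ss in run_seeds
    ]


def _run_single(
    config: RunConfig,
    maze: TopologyMaze,
    codec: ProjectedCodec,
    seed_seq: np.random.SeedSequence,
) -> RunResult:
    action_ss, tie_ss, net_ss, replay_ss = seed_seq.spawn(4)
    action_rng = np.random.default_rng(action_ss)
    tie_rng = np.random.default_rng(tie_ss)
    replay_rng = np.random.default_rng(replay_ss)
    net_seed = int(net_ss.generate_state(1)[0] % (2**31))

    nxt, rew, term = maze.transition_tables
    start = maze.state_index(maze.start_state)
    timeout = maze.timeout
    visited = np.zeros(maze.n_states, dtype=bool)
    latencies = np.empty(config.trials, dtype=np.int64)
    diagnostics: dict = {}

    if config.algorithm == "ec":
        agent = _ECRunner(config, codec)
    elif config.algorithm == "online_dqn":
        agent = _OnlineRunner(config, maze, codec, net_seed)
    else:
        agent = _DQNRunner(config, maze, codec, net_seed, replay_rng)

    for trial in range(config.trials):
        s = start
        visited[s] = True
        steps = 0
        for _ in range(timeout):
            q = agent.q_values(s)
            a = epsilon_greedy(q, config.epsilon, action_rng, tie_rng)
            s2 = nxt[s, a]
            r = rew[s, a]
            done = term[s, a]
            steps += 1
            visited[s2] = True
            agent.observe(s, a, s2, r, done)
            s = s2
            if done:
                break
        latencies[trial] = steps
        agent.end_trial(trial)

    agent.finalize(diagnostics)
    return RunResult(
        latencies=latencies,
        visited=np.flatnonzero(visited),
        q_table=agent.snapshot(maze),
        replay_diagnostics=diagnostics,
    )


class _ECRunner:
    """Episodic control: trial-end max-updates of the projected-key table."""

    def __init__(self, config: RunConfig, codec: ProjectedCodec):
        self.memory = ECMemory(
            codec,
            k=config.k_neighbors,
            capacity=config.ec_capacity,
            gamma=config.gamma,
        )
        self._trace: list[ExperienceTuple] = []
        self._q_cache: dict[int, np.ndarray] = {}

    def q_values(self, s: int) -> np.ndarray:
        q = self._q_cache.get(s)
        if q is None:
            q = self.memory.q_values_by_index(s)
            self._q_cache[s] = q
        return q

    def observe(self, s, a, s2, r, done):
        self._trace.append(ExperienceTuple(s, a, s2, r, done))

    def end_trial(self, trial):
        if self._trace:
            self.memory.update_from_trace(EpisodeTrace(self._trace))
        self._trace = []
        self._q_cache.clear()  # memory changed; cached values are stale

    def finalize(self, diagnostics):
        diagnostics["ec_entries"] = len(self.memory)

    def snapshot(self, maze):
        return self.memory.snapshot(maze)


class _NetRunnerBase:
    def __init__(self, config: RunConfig, maze: TopologyMaze, codec, net_seed: int):
        self.config = config
        if config.approximator == "tabular":
            self.obs = deep_q.one_hot_observations(maze.n_states)
        else:
            self.obs = codec.encoder.all_observations
        self.net = deep_q.make_approximator(
            config.approximator, self.obs.shape[1], maze.n_states, seed=net_seed
        )
        self.target = self.net.clone()
        self.opt = deep_q.make_optimizer(
            config.optimizer, self.net.params, config.learning_rate
        )

    def q_values(self, s: int) -> np.ndarray:
        return self.net.forward(self.obs[s][None, :])[0]

    def snapshot(self, maze):
        return self.net.forward(self.obs)

    def finalize(self, diagnostics):
        pass


class _OnlineRunner(_NetRunnerBase):
    """Online learning: each tuple trains once, nothing is stored."""

    def observe(self, s, a, s2, r, done):
        deep_q.online_update(
            self.net,
            self.target,
            self.opt,
            ExperienceTuple(s, a, s2, r, done),
            self.obs,
            self.config.gamma,
        )
        deep_q.soft_update(self.target, self.net, self.config.soft_alpha)

    def end_trial(self, trial):
        pass


class _DQNRunner(_NetRunnerBase):
    """Replay learning: per-step uniform replay or trial-end replay events."""

    def __init__(self, config, maze, codec, net_seed, replay_rng):
        super().__init__(config, maze, codec, net_seed)
        self.rng = replay_rng
        self.step_count = 0
        self.mode = config.replay_mode
        if self.mode == "per_step_random":
            self.buffer = deep_q.ReplayBuffer(config.buffer_capacity)
            self.schedule = deep_q.update_schedule(config.replay_variant)
        else:
            self.store = sfma_replay.ExperienceStore(
                maze,
                sigma=config.sigma,
                lambda_r=config.lambda_r,
                lambda_i=config.lambda_i,
            )
            self._event_similarities: list[float] = []
            self._sequence_lengths: list[np.ndarray] = []

    def observe(self, s, a, s2, r, done):
        if self.mode == "per_step_random":
            self.buffer.add(ExperienceTuple(s, a, s2, r, done))
            if self.schedule.due(self.step_count):
                deep_q.replay_update(
                    self.net,
                    self.target,
                    self.opt,
                    self.buffer,
                    self.obs,
                    self.config.gamma,
                    self.rng,
                    self.schedule.batch_size,
                )
                deep_q.soft_update(self.target, self.net, self.config.soft_alpha)
            self.step_count += 1
        else:
            self.store.add(s, a, s2, r, done)
            self._last_state = s2  # trial-end replay initiates here

    def end_trial(self, trial):
        if self.mode == "per_step_random" or len(self.store) == 0:
            return
        if self.mode == "trial_end_random":
            event = sfma_replay.random_replay_event(
                self.store, self.config.n_batches, self.config.batch_size, self.rng
            )
        else:
            event = sfma_replay.generate_replay_event(
                self.store,
                self.config.n_batches,
                self.config.batch_size,
                beta=self.config.beta,
                mode="reverse",
                rng=self.rng,
                start_state=self._last_state,
            )
        for s, a, s2, r, term in event.experience_arrays(self.store):
            targets = deep_q.td_targets(
                r, self.obs[s2], term, self.target, self.config.gamma
            )
            deep_q.train_on_batch(self.net, self.opt, self.obs[s], a, targets)
            deep_q.soft_update(self.target, self.net, self.config.soft_alpha)
        if trial < self.config.similarity_window:
            self._event_similarities.append(event_similarity(event))
            self._sequence_lengths.append(
                sfma_replay.sequence_lengths(event, self.store)
            )

    def finalize(self, diagnostics):
        if self.mode != "per_step_random":
            sims = [s for s in self._event_similarities if not np.isnan(s)]
            diagnostics["event_similarity"] = float(np.mean(sims)) if sims else np.nan
            if self._sequence_lengths:
                cat = np.concatenate(self._sequence_lengths)
                diagnostics["mean_sequence_length"] = float(cat.mean())


# -- analyses -------------------------------------------------------------


def learning_curve(results: Sequence[RunResult]):
    """Trialwise mean and standard deviation of escape latency across runs."""
    if not results:
        raise ValueError("no runs")
    lat = np.stack([r.latencies for r in results])
    return lat.mean(axis=0), lat.std(axis=0)


def auc_learning_speed(
    results: Sequence[RunResult], window: int = DEFAULT_AUC_WINDOW
) -> np.ndarray:
    """Per-run area under the latency curve over the first ``window``
    trials (lower = faster learning)."""
    return np.array([r.latencies[:window].sum() for r in results], dtype=float)


#: exploration rate of the standard test-trial protocol.  Test trials keep
#: the behavioural epsilon: a purely greedy rollout can lock into a two-step
#: argmax cycle of an under-trained value function and report a spurious
#: timeout, which the modelled test protocol does not exhibit for trained
#: replay agents; the small noise lets shallow cycles break while genuinely
#: unlearned policies still time out.
TEST_EPSILON = 0.1


def test_trial(
    maze: TopologyMaze,
    q_table: np.ndarray,
    start_index: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    epsilon: float = 0.0,
):
    """Value-guided rollout from a state, capped at the timeout.

    Greedy (``epsilon=0``) by default; study-level analyses pass
    :data:`TEST_EPSILON`.  Returns ``(state_index_sequence, latency,
    timed_out)``; the sequence includes the start state and every state
    entered.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    nxt, _, term = maze.transition_tables
    s = maze.state_index(maze.start_state) if start_index is None else start_index
    trajectory = [s]
    if s // 4 == maze.goal_node:  # already at the goal
        return trajectory, 0, False
    for steps in range(1, maze.timeout + 1):
        if epsilon > 0.0 and rng.random() < epsilon:
            a = int(rng.integers(0, N_ACTIONS))
        else:
            a = greedy_action(q_table[s], rng)
        done = term[s, a]
        s = nxt[s, a]
        trajectory.append(s)
        if done:
            return trajectory, steps, False
    return trajectory, maze.timeout, True


def solution_state_analysis(
    maze: TopologyMaze,
    q_table: np.ndarray,
    visited: np.ndarray,
    rng: Optional[np.random.Generator] = None,
) -> SolutionStateReport:
    """Label every visited state by whether the greedy agent reaches the
    goal from it within the timeout."""
    rng = np.random.default_rng(0) if rng is None else rng
    solution_map = np.zeros(maze.n_states, dtype=bool)
    for s in np.asarray(visited):
        _, _, timed_out = test_trial(maze, q_table, int(s), rng, epsilon=TEST_EPSILON)
        solution_map[s] = not timed_out
    n_solution = int(solution_map.sum())
    n_visited = len(visited)
    return SolutionStateReport(
        never_visited=maze.n_states - n_visited,
        visited_non_solution=n_visited - n_solution,
        solution=n_solution,
        solution_map=solution_map,
    )


def route_classification(
    trajectory: Sequence[int], maze: TopologyMaze, timed_out: bool
) -> str:
    """``timeout`` | ``tunnel`` (any tunnel-interior node touched) | ``open``."""
    if timed_out:
        return "timeout"
    nodes = {s // 4 for s in trajectory}
    if nodes & maze.tunnel_nodes:
        return "tunnel"
    return "open"


def route_fractions(maze: TopologyMaze, results: Sequence[RunResult], seed: int = 0):
    """Fraction of runs whose test trajectory falls in each class."""
    rng = np.random.default_rng(seed)
    counts = {"tunnel": 0, "open": 0, "timeout": 0}
    for r in results:
        traj, _, timed_out = test_trial(maze, r.q_table, rng=rng, epsilon=TEST_EPSILON)
        counts[route_classification(traj, maze, timed_out)] += 1
    n = len(results)
    return {k: v / n for k, v in counts.items()}


def batch_similarity(batch_a: np.ndarray, batch_b: np.ndarray) -> float:
    """Proportion of shared experience tuples between two equally sized
    batches (deduplicated within each batch)."""
    batch_a, batch_b = np.asarray(batch_a), np.asarray(batch_b)
    if batch_a.shape != batch_b.shape:
        raise ValueError("batch size mismatch")
    shared = np.intersect1d(batch_a, batch_b).size
    return shared / batch_a.size


def event_similarity(event) -> float:
    """Mean pairwise batch similarity over all unordered batch pairs."""
    batches = event.batches
    if len(batches) < 2:
        return float("nan")
    sims = [
        batch_similarity(batches[i], batches[j])
        for i in range(len(batches))
        for j in range(i + 1, len(batches))
    ]
    return float(np.mean(sims))


def test_latencies(
    maze: TopologyMaze,
    results: Sequence[RunResult],
    seed: int = 0,
    n_trials: int = 5,
) -> np.ndarray:
    """Per-agent test latency, averaged over ``n_trials`` seeded test
    trials from the fixed start."""
    rng = np.random.default_rng(seed)
    return np.array(
        [
            np.mean(
                [
                    test_trial(maze, r.q_table, rng=rng, epsilon=TEST_EPSILON)[1]
                    for _ in range(n_trials)
                ]
            )
            for r in results
        ]
    )


def mean_test_latency(
    maze: TopologyMaze, results: Sequence[RunResult], seed: int = 0
) -> float:
    return float(test_latencies(maze, results, seed).mean())


def relative_performance(
    seq_results: Sequence[RunResult], rand_results: Sequence[RunResult]
) -> float:
    """Mean random-replay escape latency over mean sequential-replay escape
    latency; values above 1 favour sequential replay."""
    seq = np.concatenate([r.latencies for r in seq_results]).mean()
    rand = np.concatenate([r.latencies for r in rand_results]).mean()
    return float(rand / seq)


# -- I/O ------------------------------------------------------------------


def results_to_frame(results: Sequence[RunResult]):
    """Long-format (run, trial, latency) table."""
    import pandas as pd

    rows = []
    for i, r in enumerate(results):
        for t, lat in enumerate(r.latencies):
            rows.append({"run": i, "trial": t, "latency": int(lat)})
    return pd.DataFrame(rows)


def save_results(results: Sequence[RunResult], directory, config: RunConfig) -> None:
    import json
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    results_to_frame(results).to_csv(directory / "latencies.csv", index=False)
    mean, sd = learning_curve(results)
    summary = {
        "config": {k: v for k, v in vars(config).items()},
        "mean_final_latency": float(mean[-1]),
        "auc": auc_learning_speed(results).tolist(),
    }
    (directory / "summary.json").write_text(json.dumps(summary, indent=2))
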