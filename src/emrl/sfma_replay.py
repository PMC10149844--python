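"""Biologically motivated sequential replay (SFMA-style sampler).

At the end of a trial, a replay event reactivates stored experiences one at
a time.  The probability of reactivating experience ``e`` after ``e'``
combines three factors:

* strength ``C(e) = f(n(e)) * (1 + lambda_r * rbar(e))`` — how often the
  transition was experienced and how much reward it carried on average.
  The count response ``f`` is saturating by default, ``f(n) = 1 + ln n``
  (familiarity grows sub-linearly with repetition); with a raw linear
  count the enormous spread of visit frequencies accumulated during
  exploration (1 to several hundred) drowns the similarity factor and no
  sequential structure can emerge.  ``count_weighting="linear"`` selects
  ``f(n) = n``;
* similarity ``D(e|e') = exp(-d_G / sigma)`` — a graph-distance kernel
  between anchor poses, where distance counts the agent's time steps
  (translations and rotations alike), i.e. how easily it can move from one
  pose to the other; in reverse mode the candidate's *next* state is
  anchored against the previous reactivation's *current* state, so chains
  extend backward along behaviour (the mode used for learning here);
* inhibition ``1 - I(e)`` — a just-reactivated experience is transiently
  blocked; inhibition decays multiplicatively each reactivation step.

Scores ``R = C * D * (1 - I)`` enter the sampling distribution
``p(e|e') = (exp(beta R) - 1) / sum(exp(beta R_tau) - 1)``; the ``-1``
terms pin never-visited, just-replayed and unreachable candidates to
probability exactly zero.  ``beta = 0`` is a deliberate discontinuity:
sampling is then uniform over eligible experiences, which differs from the
frequency-proportional random-replay comparator whenever visit counts are
unequal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .maze_env import TopologyMaze

DEFAULT_SIGMA = 0.5
DEFAULT_LAMBDA_R = 1.0
DEFAULT_LAMBDA_I = 0.9
DEFAULT_BATCH_SIZE = 32
#: beyond this, exp(beta*R) is computed in shifted form to avoid overflow
_EXP_SHIFT_THRESHOLD = 500.0


class ExperienceStore:
    """Deduplicated experiences with visit counts, reward tallies and
    inhibition levels, plus the precomputed graph-distance kernel."""

    def __init__(
        self,
        maze: TopologyMaze,
        sigma: float = DEFAULT_SIGMA,
        lambda_r: float = DEFAULT_LAMBDA_R,
        lambda_i: float = DEFAULT_LAMBDA_I,
        anchor: str = "state",
        count_weighting: str = "log",
    ):
        if anchor not in ("state", "node"):
            raise ValueError("anchor must be 'state' or 'node'")
        if count_weighting not in ("log", "linear"):
            raise ValueError("count_weighting must be 'log' or 'linear'")
        self.count_weighting = count_weighting
        self.maze = maze
        self.sigma = float(sigma)
        self.lambda_r = float(lambda_r)
        self.lambda_i = float(lambda_i)
        self.anchor = anchor
        d = maze.state_distances if anchor == "state" else maze.node_distances
        with np.errstate(over="ignore"):
            self._kernel = np.exp(-d / self.sigma)
        self._kernel[~np.isfinite(d)] = 0.0  # unreachable anchors
        self._index: dict[tuple[int, int, int], int] = {}
        self._s: list[int] = []
        self._a: list[int] = []
        self._s2: list[int] = []
        self._n: list[int] = []
        self._reward_sum: list[float] = []
        self._terminal: list[bool] = []
        self._dirty = True
        self.inhibition: np.ndarray = np.zeros(0)

    def __len__(self) -> int:
        return len(self._s)

    def add(self, s: int, a: int, s2: int, r: float, terminal: bool) -> int:
        """Record one occurrence; identity is the (s, a, s') triple."""
        key = (s, a, s2)
        idx = self._index.get(key)
        if idx is None:
            idx = len(self._s)
            self._index[key] = idx
            self._s.append(s)
            self._a.append(a)
            self._s2.append(s2)
            self._n.append(1)
            self._reward_sum.append(r)
            self._terminal.append(terminal)
            self._dirty = True
        else:
            self._n[idx] += 1
            self._reward_sum[idx] += r
            self._dirty = True
        return idx

    def _consolidate(self) -> None:
        """Rebuild the flat arrays (and cached strengths) after additions."""
        if not self._dirty:
            return
        self.s = np.asarray(self._s, dtype=np.int64)
        self.a = np.asarray(self._a, dtype=np.int64)
        self.s2 = np.asarray(self._s2, dtype=np.int64)
        self.terminal = np.asarray(self._terminal, dtype=bool)
        if self.anchor == "state":
            self._cur_anchor = self.s
            self._next_anchor = self.s2
        else:
            self._cur_anchor = self.s // 4
            self._next_anchor = self.s2 // 4
        self.inhibition = np.zeros(len(self._s))
        self.counts = np.asarray(self._n, dtype=float)
        self.reward_sums = np.asarray(self._reward_sum)
        mean_r = self.reward_sums / self.counts
        if self.count_weighting == "log":
            n_eff = 1.0 + np.log(self.counts)
        else:
            n_eff = self.counts
        self._strengths = n_eff * (1.0 + self.lambda_r * mean_r)
        self._dirty = False

    # -- score factors ----------------------------------------------------

    def strengths(self) -> np.ndarray:
        """C(e) for every stored experience."""
        self._consolidate()
        return self._strengths

    def strength(self, s: int, a: int, s2: int) -> float:
        """C of one candidate; exactly 0 for never-stored experiences."""
        idx = self._index.get((s, a, s2))
        if idx is None:
            return 0.0
        return float(self.strengths()[idx])

    def similarities(
        self,
        prev_idx: Optional[int],
        mode: str,
        anchor_state: Optional[int] = None,
    ) -> np.ndarray:
        """D(e|e') for all stored e given the previous reactivation.

        Reverse mode anchors each candidate's next state against the
        previous experience's current state; forward mode is the mirror.
        At event start (``prev_idx=None``) the anchor is the agent's
        current state if one is supplied (replay initiates where the
        animal is, typically the goal at trial end), otherwise D is
        identically 1.
        """
        self._consolidate()
        if prev_idx is None:
            if anchor_state is None:
                return np.ones(len(self._s))
            ref = anchor_state if self.anchor == "state" else anchor_state // 4
            if mode == "forward":
                return self._kernel[ref, self._cur_anchor]
            return self._kernel[ref, self._next_anchor]
        if mode == "reverse":
            return self._kernel[self._cur_anchor[prev_idx], self._next_anchor]
        if mode == "forward":
            return self._kernel[self._next_anchor[prev_idx], self._cur_anchor]
        if mode == "random":
            return np.ones(len(self._s))
        raise ValueError(f"unknown replay mode {mode!r}")

    def reactivation_scores(
        self,
        prev_idx: Optional[int],
        mode: str = "reverse",
        anchor_state: Optional[int] = None,
    ) -> np.ndarray:
        """R(e|e') = C(e) * D(e|e') * (1 - I(e)), nonnegative."""
        self._consolidate()
        return self.strengths() * self.similarities(prev_idx, mode, anchor_state) * (
            1.0 - self.inhibition
        )

    def reset_inhibition(self) -> None:
        self._consolidate()
        self.inhibition[:] = 0.0


def eq10_probabilities(scores: np.ndarray, beta: float) -> np.ndarray:
    """The sampling distribution over stored experiences for ``beta > 0``.

    Computed stably: for large ``beta * R`` the ``-1`` terms are negligible
    and a shifted softmax is used; zero scores keep probability exactly 0.
    """
    z = beta * np.asarray(scores, dtype=float)
    m = z.max(initial=0.0)
    if m > _EXP_SHIFT_THRESHOLD:
        w = np.exp(z - m)
        w[z <= 0.0] = 0.0
    else:
        w = np.expm1(z)
        w[w < 0.0] = 0.0
    total = w.sum()
    if total <= 0.0:
        return np.zeros_like(w)
    return w / total


def sample_next(
    scores: np.ndarray,
    beta: float,
    rng: np.random.Generator,
    eligible: Optional[np.ndarray] = None,
) -> Optional[int]:
    """Draw the next reactivation from the score vector.

    ``beta > 0``: probabilities from ``(exp(beta R) - 1)`` normalization.
    ``beta = 0``: uniform over eligible experiences (visited, not fully
    inhibited) — the stated convention, a deliberate discontinuity.
    Returns ``None`` when everything has probability zero (the event then
    terminates early).
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if beta == 0:
        if eligible is None:
            eligible = np.asarray(scores) > 0
        idx = np.flatnonzero(eligible)
        if idx.size == 0:
            return None
        return int(idx[rng.integers(0, idx.size)])
    p = eq10_probabilities(scores, beta)
    if not p.any():
        return None
    cdf = np.cumsum(p)
    return int(np.searchsorted(cdf, rng.random() * cdf[-1], side="right"))


@dataclass
class ReplayEvent:
    """Ordered batches of reactivated experience indices."""

    batches: list[np.ndarray]
    mode: str
    beta: float
    truncated: bool = False
    #: realized reactivation stream, for sequence diagnostics
    stream: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    @property
    def n_batches(self) -> int:
        return len(self.batches)

    def experience_arrays(self, store: ExperienceStore):
        """Per-batch (s, a, s2, r, terminal) arrays for the learner."""
        store._consolidate()
        mean_r = store.reward_sums / store.counts
        for batch in self.batches:
            yield (
                store.s[batch],
                store.a[batch],
                store.s2[batch],
                mean_r[batch],
                store.terminal[batch],
            )


def generate_replay_event(
    store: ExperienceStore,
    n_batches: int,
    batch_size: int = DEFAULT_BATCH_SIZE,
    beta: float = 5.0,
    mode: str = "reverse",
    rng: Optional[np.random.Generator] = None,
    start_state: Optional[int] = None,
) -> ReplayEvent:
    """One trial-end sequential replay event of ``n_batches * batch_size``
    reactivations, chunked into equally sized batches.

    Inhibition is reset at event start, set to 1 on each reactivation and
    decayed by ``lambda_i`` per step, so long events can revisit
    experiences while immediate repeats are blocked.

    Each batch is generated as its own reactivation sequence, initiated at
    the agent's current pose when ``start_state`` is given (replay starts
    where the animal is — at trial end, usually the reward site): the
    batch's first draw measures similarity to that pose, and subsequent
    draws chain from the previous reactivation.  An event is therefore a
    series of stochastic sweeps from the outcome backward along behaviour;
    with large beta the sweeps become nearly deterministic and highly
    similar to one another, with small beta they are short and diverse.
    Inhibition is reset at the start of every sequence and decays by
    ``lambda_i`` per reactivation within it, blocking immediate repeats.

    Scores are divided by the maximum strength before sampling, putting
    them on a [0, ~1] scale regardless of absolute visit counts; this
    calibrates the inverse temperature so the stated range (0 -> uniform,
    ~10 -> near-deterministic reverse chains) is meaningful for any amount
    of training history.
    """
    if len(store) == 0:
        raise ValueError("cannot replay from an empty store")
    rng = np.random.default_rng() if rng is None else rng
    scale = store.strengths().max()
    total = n_batches * batch_size
    stream = np.empty(total, dtype=np.int64)
    truncated = False
    count = 0
    for _ in range(n_batches):
        store.reset_inhibition()
        prev: Optional[int] = None
        for _ in range(batch_size):
            scores = (
                store.reactivation_scores(prev, mode, anchor_state=start_state)
                / scale
            )
            eligible = store.inhibition < 1.0
            idx = sample_next(scores, beta, rng, eligible=eligible)
            if idx is None:
                truncated = True
                break
            stream[count] = idx
            count += 1
            store.inhibition *= store.lambda_i
            store.inhibition[idx] = 1.0
            prev = idx
        if truncated:
            break
    stream = stream[:count]
    # only whole batches are emitted; early termination shortens the event
    batches = [
        stream[i : i + batch_size]
        for i in range(0, count - count % batch_size, batch_size)
    ]
    return ReplayEvent(batches, mode, beta, truncated, stream)


def random_replay_event(
    store: ExperienceStore,
    n_batches: int,
    batch_size: int = DEFAULT_BATCH_SIZE,
    rng: Optional[np.random.Generator] = None,
) -> ReplayEvent:
    """Trial-end random-replay comparator: independent draws with
    probability proportional to each experience's visit count, in the same
    event geometry as sequential replay."""
    if len(store) == 0:
        raise ValueError("cannot replay from an empty store")
    rng = np.random.default_rng() if rng is None else rng
    store._consolidate()
    p = store.counts / store.counts.sum()
    total = n_batches * batch_size
    cdf = np.cumsum(p)
    stream = np.searchsorted(cdf, rng.random(total) * cdf[-1], side="right").astype(
        np.int64
    )
    batches = [stream[i : i + batch_size] for i in range(0, total, batch_size)]
    return ReplayEvent(batches, "random", 0.0, False, stream)


def sequence_lengths(event: ReplayEvent, store: ExperienceStore) -> np.ndarray:
    """Lengths of maximal chains of consecutive adjacent reactivations.

    In reverse mode a successor extends the chain when its next state is
    the previous reactivation's current state (behavioural predecessor);
    forward mode mirrors this.
    """
    store._consolidate()
    stream = event.stream
    if stream.size == 0:
        return np.zeros(0, dtype=np.int64)
    if event.mode == "forward":
        linked = store.s2[stream[:-1]] == store.s[stream[1:]]
    else:
        linked = store.s[stream[:-1]] == store.s2[stream[1:]]
    lengths = []
    run = 1
    for ok in linked:
        if ok:
            run += 1
        else:
            lengths.append(run)
            run = 1
    lengths.append(run)
    return np.asarray(lengths, dtype=np.int64)
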