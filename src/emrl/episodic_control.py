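"""One-shot learning: model-free episodic control.

A projected-state-keyed table of action values is updated once at the end
of each trial: the value of every (state, action) pair in the trial's
trace is raised to the discounted return realized from that point, and is
never lowered.  A single successful trial therefore suffices to install a
complete start-to-goal solution, and a better route replaces a worse one
the first time it is experienced.

Acting on a state never seen before falls back to the mean value of the
k nearest stored states in the projected observation space (Euclidean
distance, KD-tree index); exact revisits are byte-exact dictionary hits
because the observation codec is deterministic.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .experience import EpisodeTrace
from .maze_env import N_ACTIONS

DEFAULT_CAPACITY = 50_000
DEFAULT_K = 5


def discounted_returns(rewards: Sequence[float], gamma: float) -> np.ndarray:
    """Backward-accumulated discounted returns R_t of one episode.

    ``R_t = sum_{tau=t+1..T} gamma^(tau-t-1) r_tau`` for the reward
    sequence ``r_1 .. r_T`` (reward index t+1 follows state/action index t).
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    rewards = np.asarray(rewards, dtype=float)
    out = np.empty_like(rewards)
    acc = 0.0
    for i in range(len(rewards) - 1, -1, -1):
        acc = rewards[i] + gamma * acc
        out[i] = acc
    return out


@dataclass
class UpdateReport:
    """Bookkeeping of one trial-end table update."""

    created: int = 0
    raised: int = 0
    unchanged: int = 0
    evicted: int = 0


class ECMemory:
    """Projected-state-keyed Q table with k-NN generalization.

    Parameters
    ----------
    codec
        A :class:`~emrl.observation_codec.ProjectedCodec`; supplies the
        projected vector of each state index.
    k
        Neighbour count for the unseen-state bootstrap (default 5).
    capacity
        Maximum number of (state, action) entries; least-recently-updated
        entries are evicted first when it binds.
    gamma
        Discount used for the trial-end returns.
    missing_action
        How a neighbour lacking a value for the queried action contributes
        to the k-NN mean: ``"zero"`` (default 0) or ``"skip"``.
    """

    def __init__(
        self,
        codec,
        k: int = DEFAULT_K,
        capacity: int = DEFAULT_CAPACITY,
        gamma: float = 0.9,
        missing_action: str = "zero",
    ):
        if missing_action not in ("zero", "skip"):
            raise ValueError("missing_action must be 'zero' or 'skip'")
        self.codec = codec
        self.k = int(k)
        self.capacity = int(capacity)
        self.gamma = float(gamma)
        self.missing_action = missing_action
        # (key bytes, action) -> value, in least-recently-updated order
        self._entries: "OrderedDict[tuple[bytes, int], float]" = OrderedDict()
        # key bytes -> (projected vector, per-action values with NaN = unset)
        self._states: dict[bytes, np.ndarray] = {}
        self._state_vecs: dict[bytes, np.ndarray] = {}
        self._tree: Optional[cKDTree] = None
        self._tree_keys: list[bytes] = []
        self._dirty = False
        self._key_cache: dict[int, bytes] = {}

    # -- keys -------------------------------------------------------------

    def key_of_index(self, state_index: int) -> bytes:
        key = self._key_cache.get(state_index)
        if key is None:
            key = np.ascontiguousarray(
                self.codec.projected_by_index(state_index)
            ).tobytes()
            self._key_cache[state_index] = key
        return key

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def n_states(self) -> int:
        return len(self._states)

    # -- updates ----------------------------------------------------------

    def update_from_trace(self, trace: EpisodeTrace) -> UpdateReport:
        """Trial-end max-update from one episode trace.

        Unseen pairs get the realized return; existing entries are raised
        to it if larger and never decreased.
        """
        report = UpdateReport()
        returns = discounted_returns(trace.rewards, self.gamma)
        for tup, r_t in zip(trace, returns):
            key = self.key_of_index(tup.state)
            self._set_max(key, tup.state, tup.action, float(r_t), report)
        self._enforce_capacity(report)
        return report

    def _set_max(self, key, state_index, action, value, report):
        vals = self._states.get(key)
        if vals is None:
            vals = np.full(N_ACTIONS, np.nan)
            self._states[key] = vals
            self._state_vecs[key] = np.ascontiguousarray(
                self.codec.projected_by_index(state_index)
            )
            self._dirty = True
        entry = (key, action)
        if np.isnan(vals[action]):
            vals[action] = value
            self._entries[entry] = value
            report.created += 1
        elif value > vals[action]:
            vals[action] = value
            self._entries[entry] = value
            self._entries.move_to_end(entry)
            report.raised += 1
        else:
            report.unchanged += 1

    def _enforce_capacity(self, report: UpdateReport) -> None:
        while len(self._entries) > self.capacity:
            (key, action), _ = self._entries.popitem(last=False)
            self._states[key][action] = np.nan
            report.evicted += 1
            if np.isnan(self._states[key]).all():
                del self._states[key]
                del self._state_vecs[key]
                self._dirty = True

    # -- lookups ----------------------------------------------------------

    def _ensure_tree(self) -> None:
        if self._dirty or self._tree is None:
            self._tree_keys = list(self._state_vecs.keys())
            if self._tree_keys:
                pts = np.stack([self._state_vecs[k] for k in self._tree_keys])
                self._tree = cKDTree(pts)
            else:
                self._tree = None
            self._dirty = False

    def q_values_by_index(self, state_index: int) -> np.ndarray:
        """All six action values for a state (exact hit or k-NN bootstrap)."""
        key = self.key_of_index(state_index)
        vals = self._states.get(key)
        if vals is not None:
            return np.nan_to_num(vals, nan=0.0)
        return self._knn_values(state_index)

    def _knn_values(self, state_index) -> np.ndarray:
        if not self._states:
            return np.zeros(N_ACTIONS)
        self._ensure_tree()
        query = np.ascontiguousarray(self.codec.projected_by_index(state_index))
        k = min(self.k, len(self._tree_keys))
        _, idx = self._tree.query(query, k=k)
        idx = np.atleast_1d(idx)
        neigh = np.stack([self._states[self._tree_keys[i]] for i in idx])
        if self.missing_action == "zero":
            return np.nanmean(np.nan_to_num(neigh, nan=0.0), axis=0)
        with np.errstate(invalid="ignore"):
            out = np.nanmean(neigh, axis=0)
        return np.nan_to_num(out, nan=0.0)

    def lookup_by_index(self, state_index: int, action: int) -> float:
        return float(self.q_values_by_index(state_index)[action])

    # -- export -----------------------------------------------------------

    def snapshot(self, maze) -> np.ndarray:
        """Greedy value table over *all* maze states, ``(n_states, 6)``."""
        out = np.empty((maze.n_states, N_ACTIONS))
        for si in range(maze.n_states):
            out[si] = self.q_values_by_index(si)
        return out

    def export_csv(self, path, maze) -> None:
        """CSV of stored entries joined through the state registry."""
        import pandas as pd
        from .maze_env import ACTIONS, HEADINGS

        rows = []
        index_of_key = {
            self.key_of_index(si): si for si in range(maze.n_states)
        }
        for (key, action), value in self._entries.items():
            si = index_of_key.get(key)
            if si is None:
                continue
            node, h = si // 4, HEADINGS[si % 4]
            rows.append(
                {"node": node, "heading": h, "action": ACTIONS[action], "q": value}
            )
        pd.DataFrame(rows).to_csv(path, index=False)


def ec_oracle(
    traces: Iterable[EpisodeTrace], gamma: float
) -> dict[tuple[int, int], float]:
    """Forward-sweep reference table over a full run's episode traces.

    For every (state, action), the value is the maximum over all of its
    occurrences of the discounted reward accumulated from that occurrence
    to the end of its episode — an independent route to the same table the
    incremental trial-end updates build.
    """
    table: dict[tuple[int, int], float] = {}
    for trace in traces:
        rewards = trace.rewards
        for i, tup in enumerate(trace):
            acc = 0.0
            for j in range(len(rewards) - 1, i - 1, -1):
                acc = rewards[j] + gamma * acc
            pair = (tup.state, tup.action)
            if pair not in table or acc > table[pair]:
                table[pair] = acc
    return table
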