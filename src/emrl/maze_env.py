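"""Parametric tunnel-maze family and its step dynamics.

The environment is a discrete topology graph: nodes are allowed positions on
an integer grid, edges are allowed transitions, and the agent's pose is a
(node, heading) pair with four headings.  A family of mazes of increasing
size shares the same structure: an open rectangular chamber at the south and
a one-node-wide tunnel corridor arcing over its north side.  The start sits
at the chamber's north-west corner (also the tunnel entrance) and the hidden
goal at the south-east corner, so two qualitatively different route classes
exist: a longer wall-constrained route through the tunnel, which funneled
exploration finds easily, and a strictly shorter route across the open
chamber, which requires more extensive exploration to discover.

Levels 1-4 grow the maze parametrically: the tunnel is elongated north-south
by one unit per level and the chamber is enlarged by one unit to the east,
one to the west and two to the south.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

HEADINGS = ("N", "E", "S", "W")
#: unit vectors (east, north) for each heading
_HEADING_VEC = {"N": (0, 1), "E": (1, 0), "S": (0, -1), "W": (-1, 0)}

ACTIONS = ("forward", "backward", "left", "right", "rotate_cw", "rotate_ccw")
N_ACTIONS = len(ACTIONS)

GOAL_REWARD = 1.0
DEFAULT_TIMEOUT = 600


class MazeConfigError(ValueError):
    """Raised when requested layout parameters violate a maze invariant."""


@dataclass(frozen=True)
class OrientedState:
    """Agent pose: a maze node plus one of four headings."""

    node_id: int
    x: int
    y: int
    heading: str

    def __post_init__(self):
        if self.heading not in HEADINGS:
            raise ValueError(f"unknown heading {self.heading!r}")


@dataclass(frozen=True)
class Transition:
    next_state: OrientedState
    reward: float
    terminal: bool


def _rot_cw(heading: str) -> str:
    return HEADINGS[(HEADINGS.index(heading) + 1) % 4]


def _rot_ccw(heading: str) -> str:
    return HEADINGS[(HEADINGS.index(heading) - 1) % 4]


class TopologyMaze:
    """Topology graph with fixed start/goal and a designated tunnel corridor.

    Parameters
    ----------
    nodes
        Integer ``(x, y)`` coordinates; x grows east, y grows north.
    edges
        Unordered node-index pairs (allowed transitions).
    start_node, goal_node
        Fixed for the maze's lifetime; ``start_node != goal_node``.
    tunnel_nodes
        Interior nodes of the one-wide corridor.
    timeout
        Trial step budget enforced by the runner (the step function itself is
        stateless and terminal only on goal entry).
    """

    def __init__(
        self,
        nodes: Sequence[tuple[int, int]],
        edges: Iterable[tuple[int, int]],
        start_node: int,
        goal_node: int,
        tunnel_nodes: Iterable[int] = (),
        timeout: int = DEFAULT_TIMEOUT,
        level: int = 0,
    ):
        self.nodes = [tuple(map(int, xy)) for xy in nodes]
        self.edges = {tuple(sorted(map(int, e))) for e in edges}
        self.start_node = int(start_node)
        self.goal_node = int(goal_node)
        self.tunnel_nodes = frozenset(int(n) for n in tunnel_nodes)
        self.timeout = int(timeout)
        self.level = int(level)
        self._coord_to_node = {xy: i for i, xy in enumerate(self.nodes)}
        self._validate()

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        n = len(self.nodes)
        if len(self._coord_to_node) != n:
            raise MazeConfigError("duplicate node coordinates")
        if self.timeout <= 0:
            raise MazeConfigError("timeout must be positive")
        for i, j in self.edges:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise MazeConfigError(f"invalid edge ({i}, {j})")
        if self.start_node == self.goal_node:
            raise MazeConfigError("start_node equals goal_node")
        for node in (self.start_node, self.goal_node):
            if not 0 <= node < n:
                raise MazeConfigError("start/goal not a maze node")
        if not nx.is_connected(self.graph):
            raise MazeConfigError("maze graph is not connected")
        for t in self.tunnel_nodes:
            if self.graph.degree(t) > 2:
                raise MazeConfigError(
                    f"tunnel node {t} has degree {self.graph.degree(t)} > 2 "
                    "(corridor property violated)"
                )
        if self.tunnel_nodes:
            direct = shortest_path_length(self, self.start_node, self.goal_node)
            tunneled = self._tunnel_constrained_length()
            if tunneled is None or not tunneled > direct:
                raise MazeConfigError(
                    "tunnel-constrained start->goal path is not strictly "
                    "longer than the unconstrained one (two-route-class "
                    "property violated)"
                )

    def _tunnel_constrained_length(self) -> Optional[int]:
        """Shortest start->goal path forced to touch the tunnel corridor."""
        best = None
        for t in self.tunnel_nodes:
            a = shortest_path_length(self, self.start_node, t)
            b = shortest_path_length(self, t, self.goal_node)
            if a is None or b is None:
                continue
            if best is None or a + b < best:
                best = a + b
        return best

    # -- structure --------------------------------------------------------

    @cached_property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(len(self.nodes)))
        g.add_edges_from(self.edges)
        return g

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_states(self) -> int:
        """Four headings per node."""
        return 4 * len(self.nodes)

    def node_at(self, x: int, y: int) -> Optional[int]:
        return self._coord_to_node.get((x, y))

    def state(self, node_id: int, heading: str) -> OrientedState:
        x, y = self.nodes[node_id]
        return OrientedState(node_id, x, y, heading)

    def state_index(self, state: OrientedState) -> int:
        return state.node_id * 4 + HEADINGS.index(state.heading)

    def state_from_index(self, idx: int) -> OrientedState:
        return self.state(idx // 4, HEADINGS[idx % 4])

    def states(self):
        for node_id in range(self.n_nodes):
            for h in HEADINGS:
                yield self.state(node_id, h)

    @property
    def start_state(self) -> OrientedState:
        return self.state(self.start_node, "N")

    def contains_state(self, state: OrientedState) -> bool:
        return (
            0 <= state.node_id < self.n_nodes
            and self.nodes[state.node_id] == (state.x, state.y)
        )

    @cached_property
    def transition_tables(self):
        """Vectorized dynamics: ``(next_state, reward, terminal)`` arrays.

        Shapes ``(n_states, 6)``, indexed by state index and action index.
        """
        S = self.n_states
        nxt = np.empty((S, N_ACTIONS), dtype=np.int64)
        rew = np.zeros((S, N_ACTIONS))
        term = np.zeros((S, N_ACTIONS), dtype=bool)
        for s in self.states():
            si = self.state_index(s)
            for ai, action in enumerate(ACTIONS):
                tr = step(self, s, action)
                nxt[si, ai] = self.state_index(tr.next_state)
                rew[si, ai] = tr.reward
                term[si, ai] = tr.terminal
        return nxt, rew, term

    @cached_property
    def node_distances(self) -> np.ndarray:
        """All-pairs shortest node-path lengths (``inf`` if unreachable)."""
        from scipy.sparse import lil_matrix
        from scipy.sparse.csgraph import shortest_path as _sp

        n = self.n_nodes
        adj = lil_matrix((n, n))
        for i, j in self.edges:
            adj[i, j] = 1
            adj[j, i] = 1
        return _sp(adj.tocsr(), method="D", unweighted=True)

    @cached_property
    def state_distances(self) -> np.ndarray:
        """All-pairs shortest path lengths between oriented states.

        Distance in the pose graph where one action (translation or
        rotation) is one step; this is the number of time steps the agent
        needs to move between poses.
        """
        from scipy.sparse import lil_matrix
        from scipy.sparse.csgraph import shortest_path as _sp

        nxt, _, _ = self.transition_tables
        S = self.n_states
        adj = lil_matrix((S, S))
        for s in range(S):
            for a in range(N_ACTIONS):
                t = nxt[s, a]
                if t != s:
                    adj[s, t] = 1
        return _sp(adj.tocsr(), method="D", unweighted=True)

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "level": self.level,
                "nodes": [list(xy) for xy in self.nodes],
                "edges": sorted(list(e) for e in self.edges),
                "start": self.start_node,
                "goal": self.goal_node,
                "tunnel": sorted(self.tunnel_nodes),
                "timeout": self.timeout,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TopologyMaze":
        d = json.loads(text)
        return cls(
            d["nodes"],
            d["edges"],
            d["start"],
            d["goal"],
            d.get("tunnel", ()),
            d.get("timeout", DEFAULT_TIMEOUT),
            d.get("level", 0),
        )

    def to_graphml(self, path) -> None:
        g = self.graph.copy()
        for i, (x, y) in enumerate(self.nodes):
            g.nodes[i]["x"] = x
            g.nodes[i]["y"] = y
            g.nodes[i]["tunnel"] = i in self.tunnel_nodes
        g.nodes[self.start_node]["role"] = "start"
        g.nodes[self.goal_node]["role"] = "goal"
        nx.write_graphml(g, path)


# -- layout parameters ----------------------------------------------------


def chamber_shape(level: int) -> tuple[int, int]:
    """(width, height) of the open chamber at a given level."""
    return 5 + 2 * (level - 1), 3 + 2 * (level - 1)


def tunnel_rise(level: int) -> int:
    """North-south elevation of the tunnel corridor above the chamber."""
    return 3 + (level - 1)


def build_tunnel_maze(
    level: int,
    chamber_width: Optional[int] = None,
    chamber_height: Optional[int] = None,
    rise: Optional[int] = None,
    timeout: int = DEFAULT_TIMEOUT,
) -> TopologyMaze:
    """Construct one member of the tunnel-maze family.

    The default layout at level ``l``: an open chamber of width
    ``W = 5 + 2(l-1)`` and height ``H = 3 + 2(l-1)`` occupying
    ``x in [0, W)``, ``y in [0, H)`` with full 4-neighbour connectivity, and
    a one-wide tunnel corridor that rises ``R = 2 + (l-1)`` units from the
    chamber's north-west node, runs east along the top row and descends
    toward the chamber's north-east node.  Start = chamber north-west node
    (the tunnel mouth); goal = the corridor's final node, one unit above
    the chamber's north-east node, which it also connects to.  The goal is
    therefore reachable two ways: the long wall-constrained corridor route,
    which funneled exploration discovers easily, and the strictly shorter
    open route across the chamber, entering the goal from the node below
    it.  Deterministic; no randomness.

    Explicit ``chamber_width``/``chamber_height``/``rise`` override the
    level defaults (the level then only labels the maze).
    """
    if level not in (1, 2, 3, 4):
        raise MazeConfigError(f"level must be in 1..4, got {level}")
    W, H = chamber_shape(level)
    if chamber_width is not None:
        W = int(chamber_width)
    if chamber_height is not None:
        H = int(chamber_height)
    R = tunnel_rise(level) if rise is None else int(rise)
    if W < 3 or H < 2 or R < 1:
        raise MazeConfigError("layout parameters out of range (W>=3, H>=2, R>=1)")

    nodes: list[tuple[int, int]] = []
    for y in range(H):
        for x in range(W):
            nodes.append((x, y))
    top = H - 1 + R
    # corridor path from the tunnel mouth to the goal, in order
    corridor = (
        [(0, y) for y in range(H, top + 1)]
        + [(x, top) for x in range(1, W)]
        + [(W - 1, y) for y in range(top - 1, H - 1, -1)]
    )
    corridor_start = len(nodes)
    nodes.extend(corridor)
    corridor_ids = list(range(corridor_start, len(nodes)))

    index = {xy: i for i, xy in enumerate(nodes)}
    edges = set()
    for y in range(H):  # chamber grid
        for x in range(W):
            i = index[(x, y)]
            if x + 1 < W:
                edges.add(tuple(sorted((i, index[(x + 1, y)]))))
            if y + 1 < H:
                edges.add(tuple(sorted((i, index[(x, y + 1)]))))
    for i, j in zip(corridor_ids, corridor_ids[1:]):  # corridor path
        edges.add(tuple(sorted((i, j))))

    # start in the tunnel mouth (west corridor foot), goal at the east
    # corridor foot; both connect down into the chamber's corner nodes
    start = corridor_ids[0]  # (0, H)
    goal = corridor_ids[-1]  # (W-1, H), one unit above the chamber NE node
    edges.add(tuple(sorted((start, index[(0, H - 1)]))))
    edges.add(tuple(sorted((goal, index[(W - 1, H - 1)]))))
    tunnel_ids = set(corridor_ids[1:-1])  # interior corridor only
    return TopologyMaze(nodes, edges, start, goal, tunnel_ids, timeout, level)


# -- dynamics -------------------------------------------------------------


def step(maze: TopologyMaze, state: OrientedState, action: str) -> Transition:
    """One environment step; pure function of ``(maze, state, action)``.

    Rotations change the heading in place.  Translations (forward/backward
    relative to heading, left/right lateral strafes) move one grid unit iff
    the corresponding edge exists, otherwise the agent stays put.  Reward is
    +1 exactly on entering the goal node, which also terminates the trial.
    """
    if action not in ACTIONS:
        raise ValueError(f"unknown action {action!r}")
    if not maze.contains_state(state):
        raise ValueError(f"state {state} is not a state of this maze")

    if action == "rotate_cw":
        nxt = maze.state(state.node_id, _rot_cw(state.heading))
    elif action == "rotate_ccw":
        nxt = maze.state(state.node_id, _rot_ccw(state.heading))
    else:
        dx, dy = _HEADING_VEC[state.heading]
        if action == "backward":
            dx, dy = -dx, -dy
        elif action == "left":
            dx, dy = -dy, dx
        elif action == "right":
            dx, dy = dy, -dx
        target = maze.node_at(state.x + dx, state.y + dy)
        if target is not None and tuple(sorted((state.node_id, target))) in maze.edges:
            nxt = maze.state(target, state.heading)
        else:
            nxt = state  # blocked translation: stay in place
    reached = nxt.node_id == maze.goal_node and state.node_id != maze.goal_node
    reward = GOAL_REWARD if reached else 0.0
    return Transition(nxt, reward, reached)


def shortest_path_length(
    maze: TopologyMaze,
    from_node: int,
    to_node: int,
    restrict_to: Optional[Iterable[int]] = None,
) -> Optional[int]:
    """BFS shortest node-path length (edges counted, rotations not).

    ``restrict_to`` confines the search to a node subset (which must contain
    both endpoints to be satisfiable).  Returns ``None`` when no path exists
    under the restriction, distinguishing unreachability from bad input.
    """
    for node in (from_node, to_node):
        if not 0 <= node < maze.n_nodes:
            raise ValueError(f"node {node} not in maze")
    g = maze.graph
    if restrict_to is not None:
        keep = set(restrict_to)
        if from_node not in keep or to_node not in keep:
            return None
        g = g.subgraph(keep)
    try:
        return nx.shortest_path_length(g, from_node, to_node)
    except nx.NetworkXNoPath:
        return None
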