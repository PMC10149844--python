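"""Deterministic per-state observation vectors and the random projection.

The agents never see the topology graph; they see a fixed, deterministic
observation vector per (node, heading) pose, standing in for a camera view
of the maze.  Two properties of visual input matter for the algorithms and
are reproduced here: (i) the mapping is injective (distinct poses give
distinct views), and (ii) it is spatially and orientationally smooth, so
that nearby poses produce nearby observations — without smoothness the
k-nearest-neighbour bootstrap of episodic control would be meaningless.

Smoothness is obtained with random Fourier features of a pose embedding
``u(s) = (embedding(node), cos(theta), sin(theta))``.  The spatial part is a
classical multidimensional scaling of the maze's *geodesic* (graph) node
distances rather than raw grid coordinates: two positions separated by a
wall look very different to a camera even when their coordinates are close,
so observation similarity follows traversal distance.  Frequencies are
drawn once from a seeded Gaussian whose bandwidth is set so that
observations of adjacent nodes (and of poses one 90-degree rotation apart)
correlate at a configurable level, 0.8 by default.

A seeded Gaussian random projection ``phi: x -> Mx`` (M with iid standard
normal entries) emulates the dimensionality-reduction stage in front of the
episodic-control memory; by the Johnson-Lindenstrauss lemma it preserves
relative distances up to a common scale.
"""

from __future__ import annotations

from functools import cached_property
from typing import Optional

import numpy as np

from .maze_env import HEADINGS, OrientedState, TopologyMaze

DEFAULT_OBS_DIM = 64
DEFAULT_ADJACENT_CORRELATION = 0.8
#: squared pose-space distance of a 90-degree rotation, |Δ(cosθ, sinθ)|² = 2
_ROT90_SQ = 2.0


class StateEncoder:
    """Seeded deterministic encoder from oriented states to observations.

    Parameters
    ----------
    maze
        The owning maze (fixes the coordinate normalization).
    dim
        Observation dimension D (default 64).
    seed
        Seed of the random-feature frequencies; identical ``(maze, seed)``
        give identical observations.
    adjacent_correlation
        Target kernel value between observations of adjacent nodes (one
        traversal step apart) and of 90-degree rotations at a node.
    embed_dim
        Dimension of the geodesic spatial embedding.
    """

    def __init__(
        self,
        maze: TopologyMaze,
        dim: int = DEFAULT_OBS_DIM,
        seed: int = 0,
        adjacent_correlation: float = DEFAULT_ADJACENT_CORRELATION,
        embed_dim: int = 8,
    ):
        if not 0 < adjacent_correlation < 1:
            raise ValueError("adjacent_correlation must be in (0, 1)")
        self.maze = maze
        self.dim = int(dim)
        self.seed = int(seed)
        self.adjacent_correlation = float(adjacent_correlation)
        self.embed_dim = int(embed_dim)
        self._embedding = self._geodesic_embedding(maze, self.embed_dim)

        # Gaussian kernel exp(-|du|^2 / (2 l^2)) = rho at the reference
        # separations: one traversal step spatially (the embedding is scaled
        # to unit mean edge length), 90 degrees in heading.
        log_inv_rho = -np.log(self.adjacent_correlation)
        l_sp = 1.0 / np.sqrt(2.0 * log_inv_rho)
        l_h = np.sqrt(_ROT90_SQ) / np.sqrt(2.0 * log_inv_rho)
        rng = np.random.default_rng(self.seed)
        scales = np.concatenate(
            [np.full(self.embed_dim, 1.0 / l_sp), [1.0 / l_h, 1.0 / l_h]]
        )
        self._freqs = rng.standard_normal((self.dim, self.embed_dim + 2)) * scales
        self._phases = rng.uniform(0.0, 2.0 * np.pi, size=self.dim)

    @staticmethod
    def _geodesic_embedding(maze: TopologyMaze, embed_dim: int) -> np.ndarray:
        """Classical MDS of graph distances, scaled to unit mean edge length.

        Deterministic given the maze; positions separated by walls end up
        far apart even when their grid coordinates are close.
        """
        d = maze.node_distances
        n = maze.n_nodes
        center = np.eye(n) - 1.0 / n
        gram = -0.5 * center @ (d * d) @ center
        w, v = np.linalg.eigh(gram)
        order = np.argsort(w)[::-1][:embed_dim]
        emb = v[:, order] * np.sqrt(np.maximum(w[order], 0.0))
        edge_lengths = [np.linalg.norm(emb[i] - emb[j]) for i, j in maze.edges]
        return emb / np.mean(edge_lengths)

    def _pose(self, state: OrientedState) -> np.ndarray:
        theta = {"N": 0.5 * np.pi, "E": 0.0, "S": 1.5 * np.pi, "W": np.pi}[
            state.heading
        ]
        return np.concatenate(
            [self._embedding[state.node_id], [np.cos(theta), np.sin(theta)]]
        )

    def encode(self, state: OrientedState) -> np.ndarray:
        """Observation vector of one state (cached table row)."""
        if not self.maze.contains_state(state):
            raise ValueError(f"state {state} is not a state of the owning maze")
        return self.all_observations[self.maze.state_index(state)]

    @cached_property
    def all_observations(self) -> np.ndarray:
        """The full (n_states, D) observation table, built once."""
        poses = np.stack([self._pose(s) for s in self.maze.states()])
        z = poses @ self._freqs.T + self._phases
        return np.sqrt(2.0 / self.dim) * np.cos(z)

    def dump_h5(self, path) -> None:
        """Write the state -> observation table keyed by (node, heading)."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("observations", data=self.all_observations)
            f.create_dataset(
                "node", data=np.repeat(np.arange(self.maze.n_nodes), 4)
            )
            f.create_dataset(
                "heading",
                data=np.array(list(HEADINGS) * self.maze.n_nodes, dtype="S1"),
            )
            f.attrs["dim"] = self.dim
            f.attrs["seed"] = self.seed


def random_projection_matrix(
    out_dim: Optional[int], in_dim: int, seed: int = 0
) -> np.ndarray:
    """Seeded (F, D) matrix with iid standard-normal entries.

    ``out_dim=None`` picks the default ``min(256, in_dim)``.
    """
    if out_dim is None:
        out_dim = min(256, in_dim)
    rng = np.random.default_rng(seed)
    return rng.standard_normal((int(out_dim), int(in_dim)))


def project(M: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Exact linear map ``x -> Mx`` (rows of x projected if 2-D)."""
    x = np.asarray(x)
    if x.shape[-1] != M.shape[1]:
        raise ValueError(
            f"dimension mismatch: M is {M.shape}, x has length {x.shape[-1]}"
        )
    return x @ M.T


class ProjectedCodec:
    """Encoder composed with the random projection, cached per state.

    After the first touch of a state, lookups are O(1) table reads; the
    whole table is precomputed eagerly since the state space is small.
    """

    def __init__(
        self,
        encoder: StateEncoder,
        projection_dim: Optional[int] = None,
        projection_seed: int = 0,
    ):
        self.encoder = encoder
        self.M = random_projection_matrix(
            projection_dim, encoder.dim, projection_seed
        )

    @property
    def dim(self) -> int:
        return self.M.shape[0]

    @cached_property
    def all_projected(self) -> np.ndarray:
        return project(self.M, self.encoder.all_observations)

    def projected(self, state: OrientedState) -> np.ndarray:
        return self.all_projected[self.encoder.maze.state_index(state)]

    def projected_by_index(self, state_index: int) -> np.ndarray:
        return self.all_projected[state_index]
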