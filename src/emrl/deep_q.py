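"""Replay learning and online learning: incremental Q-function training.

A small numpy Q-function toolkit replaces the image-scale convolutional
network of the full visual task: the approximator maps a low-dimensional
observation vector to the six action values and is trained by squared
temporal-difference error with gradient descent.  Three architectures are
provided — a one-hot tabular head (exact tabular Q-learning), a linear map
on the observation features, and a two-hidden-layer ReLU perceptron — all
sharing the online/target parameter scheme with soft target updates.

Replay learning draws mini-batches uniformly from a FIFO experience buffer
(one 32-batch update per environment step by default); online learning
consumes each experience exactly once, with no store.  Two diagnostic
replay variants isolate what makes replay fast: ``batch_size_one`` (replay
with batch 1) and ``sparse_sampling`` (a 32-batch only every 32 steps),
both reducing the training-data budget to that of online learning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .experience import ExperienceTuple
from .maze_env import N_ACTIONS

DEFAULT_LEARNING_RATE = 1e-4
DEFAULT_SOFT_ALPHA = 0.01
DEFAULT_BUFFER_CAPACITY = 50_000
DEFAULT_BATCH_SIZE = 32


# -- approximators --------------------------------------------------------


class QApproximator:
    """Interface: ``forward`` (batch of observations -> (B, 6) values),
    ``backward`` (accumulate parameter gradients of sum_i g_i * Q(x_i, a_i)),
    and flat parameter access for soft target updates."""

    params: list[np.ndarray]

    def forward(self, X: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def gradients(
        self, X: np.ndarray, actions: np.ndarray, coeffs: np.ndarray
    ) -> list[np.ndarray]:
        raise NotImplementedError

    def clone(self) -> "QApproximator":
        import copy

        other = copy.copy(self)
        other.params = [p.copy() for p in self.params]
        other._rebind()
        return other

    def _rebind(self) -> None:  # subclasses refresh any aliases into params
        pass


class LinearQ(QApproximator):
    """Q(x) = W x + b; zero-initialized (all values tie at zero at first)."""

    def __init__(self, obs_dim: int):
        self.obs_dim = int(obs_dim)
        self.params = [np.zeros((N_ACTIONS, obs_dim)), np.zeros(N_ACTIONS)]

    def forward(self, X: np.ndarray) -> np.ndarray:
        W, b = self.params
        return X @ W.T + b

    def gradients(self, X, actions, coeffs):
        dW = np.zeros_like(self.params[0])
        db = np.zeros_like(self.params[1])
        np.add.at(dW, actions, coeffs[:, None] * X)
        np.add.at(db, actions, coeffs)
        return [dW, db]


class MLPQ(QApproximator):
    """Two-hidden-layer ReLU perceptron with a linear head.

    Hidden weights use seeded He initialization; the output layer starts at
    zero so the initial value function is identically zero, like the
    tabular and linear heads.
    """

    def __init__(
        self,
        obs_dim: int,
        hidden: tuple[int, int] = (64, 64),
        seed: int = 0,
    ):
        rng = np.random.default_rng(seed)
        h1, h2 = hidden
        self.obs_dim = int(obs_dim)
        self.hidden = (int(h1), int(h2))
        self.params = [
            rng.standard_normal((h1, obs_dim)) * np.sqrt(2.0 / obs_dim),
            np.zeros(h1),
            rng.standard_normal((h2, h1)) * np.sqrt(2.0 / h1),
            np.zeros(h2),
            np.zeros((N_ACTIONS, h2)),
            np.zeros(N_ACTIONS),
        ]

    def _hidden_pass(self, X):
        W1, b1, W2, b2, _, _ = self.params
        z1 = X @ W1.T + b1
        a1 = np.maximum(z1, 0.0)
        z2 = a1 @ W2.T + b2
        a2 = np.maximum(z2, 0.0)
        return z1, a1, z2, a2

    def forward(self, X: np.ndarray) -> np.ndarray:
        *_, a2 = self._hidden_pass(X)
        W3, b3 = self.params[4], self.params[5]
        return a2 @ W3.T + b3

    def gradients(self, X, actions, coeffs):
        W1, b1, W2, b2, W3, b3 = self.params
        z1, a1, z2, a2 = self._hidden_pass(X)
        dW3 = np.zeros_like(W3)
        db3 = np.zeros_like(b3)
        np.add.at(dW3, actions, coeffs[:, None] * a2)
        np.add.at(db3, actions, coeffs)
        da2 = coeffs[:, None] * W3[actions]
        dz2 = da2 * (z2 > 0)
        dW2 = dz2.T @ a1
        db2 = dz2.sum(axis=0)
        da1 = dz2 @ W2
        dz1 = da1 * (z1 > 0)
        dW1 = dz1.T @ X
        db1 = dz1.sum(axis=0)
        return [dW1, db1, dW2, db2, dW3, db3]


def make_approximator(
    kind: str, obs_dim: int, n_states: Optional[int] = None, seed: int = 0
) -> QApproximator:
    """Factory: ``tabular`` (one-hot linear over state indices), ``linear``
    or ``mlp``.  Tabular expects one-hot observations of length n_states."""
    if kind == "linear":
        return LinearQ(obs_dim)
    if kind == "mlp":
        return MLPQ(obs_dim, seed=seed)
    if kind == "tabular":
        if n_states is None:
            raise ValueError("tabular approximator needs n_states")
        return LinearQ(n_states)
    raise ValueError(f"unknown approximator kind {kind!r}")


def one_hot_observations(n_states: int) -> np.ndarray:
    """Identity feature table turning the linear head into a lookup table."""
    return np.eye(n_states)


# -- optimizers -----------------------------------------------------------


class SGD:
    """Plain gradient descent; used for the hand-checkable unit cases."""

    def __init__(self, params: Sequence[np.ndarray], lr: float):
        self.params = params
        self.lr = float(lr)

    def step(self, grads: Sequence[np.ndarray]) -> None:
        for p, g in zip(self.params, grads):
            p -= self.lr * g


class Adam:
    """Adaptive-moment gradient descent (beta1=0.9, beta2=0.999)."""

    def __init__(
        self,
        params: Sequence[np.ndarray],
        lr: float = DEFAULT_LEARNING_RATE,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def make_optimizer(kind: str, params, lr: float):
    if kind == "adam":
        return Adam(params, lr)
    if kind == "sgd":
        return SGD(params, lr)
    raise ValueError(f"unknown optimizer {kind!r}")


# -- replay buffer --------------------------------------------------------


class ReplayBuffer:
    """FIFO store of experience tuples with uniform with-replacement sampling."""

    def __init__(self, capacity: int = DEFAULT_BUFFER_CAPACITY):
        self.capacity = int(capacity)
        self._s = np.empty(self.capacity, dtype=np.int64)
        self._a = np.empty(self.capacity, dtype=np.int64)
        self._s2 = np.empty(self.capacity, dtype=np.int64)
        self._r = np.empty(self.capacity)
        self._term = np.empty(self.capacity, dtype=bool)
        self._size = 0
        self._head = 0

    def __len__(self) -> int:
        return self._size

    def add(self, tup: ExperienceTuple) -> None:
        i = self._head
        self._s[i] = tup.state
        self._a[i] = tup.action
        self._s2[i] = tup.next_state
        self._r[i] = tup.reward
        self._term[i] = tup.terminal
        self._head = (i + 1) % self.capacity
        self._size = min(self._size + 1, self.capacity)

    def sample(self, batch_size: int, rng: np.random.Generator):
        """Uniform over stored tuples, with replacement."""
        idx = rng.integers(0, self._size, size=batch_size)
        return (
            self._s[idx],
            self._a[idx],
            self._s2[idx],
            self._r[idx],
            self._term[idx],
        )


# -- learning steps -------------------------------------------------------


def td_targets(
    rewards: np.ndarray,
    next_obs: np.ndarray,
    terminal: np.ndarray,
    target_net: QApproximator,
    gamma: float,
    printed_form: bool = False,
) -> np.ndarray:
    """Bootstrap targets ``r + gamma * max_a' Q_target(s', a')``.

    Terminal transitions use the bare reward.  ``printed_form=True``
    reproduces the literal published loss (no discount, no terminal mask)
    for reference comparisons.
    """
    max_next = target_net.forward(next_obs).max(axis=1)
    if printed_form:
        return rewards + max_next
    return rewards + gamma * max_next * ~np.asarray(terminal, dtype=bool)


def train_on_batch(
    net: QApproximator,
    optimizer,
    obs: np.ndarray,
    actions: np.ndarray,
    targets: np.ndarray,
) -> float:
    """One gradient step on ``L = sum_i (target_i - Q(s_i, a_i))^2``.

    Returns the loss before the update; target parameters are untouched.
    """
    q = net.forward(obs)[np.arange(len(actions)), actions]
    err = targets - q
    loss = float(err @ err)
    grads = net.gradients(obs, actions, -2.0 * err)
    optimizer.step(grads)
    return loss


def replay_update(
    net: QApproximator,
    target_net: QApproximator,
    optimizer,
    buffer: ReplayBuffer,
    obs_table: np.ndarray,
    gamma: float,
    rng: np.random.Generator,
    batch_size: int = DEFAULT_BATCH_SIZE,
) -> Optional[float]:
    """Draw a mini-batch from the buffer and take one gradient step.

    Empty buffer is a logged no-op (returns ``None``).
    """
    if len(buffer) == 0:
        return None
    s, a, s2, r, term = buffer.sample(batch_size, rng)
    targets = td_targets(r, obs_table[s2], term, target_net, gamma)
    return train_on_batch(net, optimizer, obs_table[s], a, targets)


def online_update(
    net: QApproximator,
    target_net: QApproximator,
    optimizer,
    tup: ExperienceTuple,
    obs_table: np.ndarray,
    gamma: float,
    printed_form: bool = False,
) -> float:
    """Single-tuple squared TD-error step; the tuple is never stored.

    ``printed_form=True`` reproduces the literal published single-sample
    loss, in which the online and target networks swap roles and the
    discount is absent.
    """
    obs = obs_table[tup.state][None, :]
    next_obs = obs_table[tup.next_state][None, :]
    if printed_form:
        target = float(tup.reward + net.forward(next_obs).max())
        q = target_net.forward(obs)[0, tup.action]
        err = target - q
        loss = float(err * err)
        grads = target_net.gradients(obs, np.array([tup.action]), np.array([-2.0 * err]))
        optimizer.step(grads)
        return loss
    target = td_targets(
        np.array([tup.reward]),
        next_obs,
        np.array([tup.terminal]),
        target_net,
        gamma,
    )
    return train_on_batch(net, optimizer, obs, np.array([tup.action]), target)


def soft_update(
    target_net: QApproximator, net: QApproximator, alpha: float = DEFAULT_SOFT_ALPHA
) -> None:
    """Polyak averaging ``w_target += alpha * (w - w_target)``, elementwise."""
    if len(target_net.params) != len(net.params):
        raise ValueError("parameter list length mismatch")
    for pt, p in zip(target_net.params, net.params):
        if pt.shape != p.shape:
            raise ValueError(f"shape mismatch {pt.shape} vs {p.shape}")
        pt += alpha * (p - pt)


def save_params(net: QApproximator, path) -> None:
    """Checkpoint the parameter arrays to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        for i, p in enumerate(net.params):
            f.create_dataset(f"param_{i}", data=p)


def load_params(net: QApproximator, path) -> None:
    import h5py

    with h5py.File(path, "r") as f:
        for i, p in enumerate(net.params):
            p[...] = f[f"param_{i}"][...]


# -- update scheduling ----------------------------------------------------


@dataclass(frozen=True)
class UpdateSchedule:
    """Per-step replay plan: a ``batch_size`` sample every ``period`` steps."""

    batch_size: int
    period: int

    def due(self, step_count: int) -> bool:
        return step_count % self.period == 0


def update_schedule(variant: str) -> UpdateSchedule:
    """``default`` = 32-batch each step; ``batch_size_one`` = 1-batch each
    step; ``sparse_sampling`` = 32-batch every 32 steps.  The two variants
    match online learning's per-step data budget."""
    if variant == "default":
        return UpdateSchedule(DEFAULT_BATCH_SIZE, 1)
    if variant == "batch_size_one":
        return UpdateSchedule(1, 1)
    if variant == "sparse_sampling":
        return UpdateSchedule(DEFAULT_BATCH_SIZE, DEFAULT_BATCH_SIZE)
    raise ValueError(f"unknown replay variant {variant!r}")
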