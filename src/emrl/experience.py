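"""The experience tuple — the shared unit of memory, replay and learning.

Experiences are kept at the level of state *indices* (``node*4 + heading``)
so that every consumer (episodic control, the replay buffer, the sequential
replay sampler) can use flat integer arrays; observation vectors are looked
up through the codec when a learner needs them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence


@dataclass(frozen=True)
class ExperienceTuple:
    """One ``(s_t, a_t, s_{t+1}, r_{t+1})`` record with a terminal flag."""

    state: int
    action: int
    next_state: int
    reward: float
    terminal: bool = False


class EpisodeTrace:
    """Ordered experiences of one trial; consecutive tuples must chain."""

    def __init__(self, tuples: Sequence[ExperienceTuple], timeout: int | None = None):
        tuples = list(tuples)
        for prev, cur in zip(tuples, tuples[1:]):
            if prev.next_state != cur.state:
                raise ValueError("trace tuples do not chain (s_{t+1} != next s_t)")
            if prev.terminal:
                raise ValueError("terminal tuple before the end of the trace")
        if timeout is not None and len(tuples) > timeout:
            raise ValueError(f"trace longer than the {timeout}-step budget")
        self._tuples = tuples

    def __len__(self) -> int:
        return len(self._tuples)

    def __iter__(self) -> Iterator[ExperienceTuple]:
        return iter(self._tuples)

    def __getitem__(self, i):
        return self._tuples[i]

    @property
    def rewards(self) -> list[float]:
        return [t.reward for t in self._tuples]

    @property
    def successful(self) -> bool:
        return bool(self._tuples) and self._tuples[-1].terminal
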