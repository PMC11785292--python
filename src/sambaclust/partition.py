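"""Set partitions over a finite ground set of string labels.

A :class:`Partition` is an immutable collection of disjoint, nonempty
blocks whose union is the ground set.  Partitions are produced by the
per-subject dendrogram cut, by the cross-subject consensus step, and by
the Monte-Carlo null sampler; they compare equal irrespective of block
order or within-block order.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Sequence

import numpy as np

__all__ = ["Partition"]


class Partition:
    """A partition of a finite set of hashable labels into disjoint blocks."""

    __slots__ = ("_blocks", "_index")

    def __init__(self, blocks: Iterable[Iterable[str]]):
        canon = []
        seen: dict[str, int] = {}
        for b in blocks:
            fb = tuple(sorted(set(b)))
            if not fb:
                raise ValueError("partition blocks must be nonempty")
            for item in fb:
                if item in seen:
                    raise ValueError(f"item {item!r} appears in more than one block")
                seen[item] = len(canon)
            canon.append(fb)
        # canonical order: by smallest element of each block
        order = sorted(range(len(canon)), key=lambda i: canon[i][0])
        self._blocks = tuple(canon[i] for i in order)
        self._index = {item: k for k, blk in enumerate(self._blocks) for item in blk}

    @property
    def blocks(self) -> tuple[tuple[str, ...], ...]:
        return self._blocks

    @property
    def items(self) -> frozenset[str]:
        return frozenset(self._index)

    @property
    def n_blocks(self) -> int:
        return len(self._blocks)

    def block_of(self, item: str) -> int:
        """Index (in canonical block order) of the block containing ``item``."""
        return self._index[item]

    def co_clustered(self, u: str, v: str) -> bool:
        return self._index[u] == self._index[v]

    def to_labels(self, order: Sequence[str]) -> np.ndarray:
        """Integer block labels aligned with ``order`` (one per item)."""
        return np.array([self._index[u] for u in order], dtype=np.int64)

    @classmethod
    def from_labels(cls, order: Sequence[str], labels: Sequence[int]) -> "Partition":
        if len(order) != len(labels):
            raise ValueError("order and labels must have equal length")
        groups: dict[int, list[str]] = {}
        for item, lab in zip(order, labels):
            groups.setdefault(int(lab), []).append(item)
        return cls(groups.values())

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {"blocks": [list(b) for b in self._blocks]}

    @classmethod
    def from_dict(cls, d: dict) -> "Partition":
        return cls(d["blocks"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Partition":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    # -- dunder -----------------------------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self._blocks == other._blocks

    def __hash__(self) -> int:
        return hash(self._blocks)

    def __len__(self) -> int:
        return len(self._blocks)

    def __iter__(self):
        return iter(self._blocks)

    def __repr__(self) -> str:
        inner = ", ".join("{" + ",".join(b) + "}" for b in self._blocks)
        return f"Partition({inner})"
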