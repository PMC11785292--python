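"""The "samba" stochastic chain of auditory stimuli.

The stimulus alphabet is ``{0, 1, 2}``: 0 a silent unit, 1 a weak beat,
2 a strong beat.  Starting from ``X_0 = 2``, the next symbol depends on
how long ago the last strong beat occurred (``T_n`` = index of the most
recent strong beat at or before ``n``):

* ``T_n = n`` or ``n - 2``: the next symbol is 1 with probability 0.8,
  otherwise 0;
* ``T_n = n - 1``: the next symbol is 0;
* ``T_n = n - 3``: the next symbol is 2.

The strong beat is therefore deterministic with period 4 (it occurs at
every index divisible by 4), and its occurrence is a renewal point: the
law of the future given a strong beat does not depend on the earlier
past.  A typical realisation looks like ``21012001210020002``.

The 12 distinct three-symbol windows that can occur in such sequences
form the ground set ``U``; their grouping by the position (or absence)
of the strong beat is the reference partition ``P*``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .partition import Partition

__all__ = [
    "ALPHABET",
    "StimulusSequence",
    "simulate_chain",
    "enumerate_strings",
    "strong_beat_partition",
    "label_windows",
]

ALPHABET = (0, 1, 2)

#: probability that a random slot (one or three steps after a strong
#: beat) is a weak beat rather than a silent unit
WEAK_BEAT_PROB = 0.8


@dataclass(frozen=True)
class StimulusSequence:
    """A realisation ``X_0 .. X_N`` of the stimulus chain."""

    symbols: np.ndarray  # int8 array of length N+1 over {0,1,2}

    def __post_init__(self):
        sym = np.asarray(self.symbols, dtype=np.int8)
        object.__setattr__(self, "symbols", sym)
        if sym.ndim != 1 or sym.size < 1:
            raise ValueError("symbols must be a nonempty 1-d array")
        if not np.isin(sym, ALPHABET).all():
            raise ValueError("symbols must take values in {0, 1, 2}")

    def __len__(self) -> int:
        return int(self.symbols.size)

    def __str__(self) -> str:
        return "".join(str(int(s)) for s in self.symbols)

    @classmethod
    def from_string(cls, s: str) -> "StimulusSequence":
        return cls(np.fromiter((int(c) for c in s), dtype=np.int8, count=len(s)))


def simulate_chain(n_steps: int, seed: int | None = None) -> StimulusSequence:
    """Simulate ``X_0 .. X_{n_steps}`` of the stimulus chain.

    The chain starts at ``X_0 = 2`` with no burn-in.  Because the strong
    beat recurs deterministically every 4 steps, the sequence is
    ``2 a 0 b 2 a 0 b ...`` where each ``a``/``b`` slot independently is
    1 with probability 0.8 and 0 otherwise; the simulation draws those
    slots with a single PCG64 generator, consuming one uniform variate
    per random slot in index order (equivalent to the step-by-step
    ``T_n`` rules).

    Parameters
    ----------
    n_steps : number of transitions; the result has ``n_steps + 1`` symbols.
    seed : seed for :func:`numpy.random.default_rng`.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    n = n_steps + 1
    rng = np.random.default_rng(seed)
    sym = np.zeros(n, dtype=np.int8)
    sym[0::4] = 2
    random_slots = np.flatnonzero(np.arange(n) % 2 == 1)  # indices 1, 3 mod 4
    draws = rng.random(random_slots.size) < WEAK_BEAT_PROB
    sym[random_slots] = draws.astype(np.int8)
    return StimulusSequence(sym)


def enumerate_strings() -> list[str]:
    """All three-symbol strings occurring with positive probability.

    Enumerated by traversing the chain's deterministic phase structure:
    the symbol at index ``n`` is 2 if ``n % 4 == 0``, 0 if ``n % 4 == 2``,
    and either 0 or 1 otherwise.  Returns the 12 reachable windows in
    lexicographic order.
    """
    per_phase = {0: ("2",), 1: ("0", "1"), 2: ("0",), 3: ("0", "1")}
    found: set[str] = set()
    for start in range(4):
        opts = [per_phase[(start + k) % 4] for k in range(3)]
        for a in opts[0]:
            for b in opts[1]:
                for c in opts[2]:
                    found.add(a + b + c)
    return sorted(found)


def strong_beat_partition() -> Partition:
    """The reference partition ``P*`` of the 12 strings.

    Strings are grouped by the position of the strong beat (symbol 2)
    within the window, or its absence::

        {000,001,101,100}, {200,210}, {020,021,120,121}, {002,012}
    """
    groups: dict[int, list[str]] = {-1: [], 0: [], 1: [], 2: []}
    for u in enumerate_strings():
        groups[u.find("2")].append(u)
    return Partition([groups[-1], groups[0], groups[1], groups[2]])


def label_windows(seq: StimulusSequence) -> dict[int, str]:
    """Map each index ``n >= 2`` to the window ``(X_{n-2}, X_{n-1}, X_n)``.

    Each stimulus epoch ``n`` is thereby assigned to exactly one string
    of ``U`` (the stimulus it ends on plus the two preceding ones).
    """
    sym = seq.symbols
    if sym.size < 3:
        raise ValueError("sequence must have at least 3 symbols")
    chars = np.char.mod("%d", sym)
    windows = np.char.add(np.char.add(chars[:-2], chars[1:-1]), chars[2:])
    return {n + 2: str(w) for n, w in enumerate(windows)}
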