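"""Independent oracles for property suites.

These deliberately avoid the algorithms used by the package: the repeat
oracle is an exhaustive shift-comparison over every circular diagonal
(quadratic in genome length), and the recombination oracle enumerates raw
event sequences without breadth-first canonical pruning.
"""

from __future__ import annotations

import numpy as np

from organelle_dynamics.recombination import MoleculeState, canonicalize, \
    pair_orientation, recombine
from organelle_dynamics.seqio import CircularSequence, revcomp


def _circular_runs(eq: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a circular boolean array: (start, length)."""
    n = len(eq)
    if eq.all():
        return [(0, n)]
    m = int(np.flatnonzero(~eq)[0])
    e = np.roll(eq, -m)  # e[0] is False
    d = np.diff(e.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if e[-1]:
        ends.append(n)
    return [(int(a + m) % n, int(b - a)) for a, b in zip(starts, ends)]


def _overlap(p1: int, p2: int, length: int, n: int) -> bool:
    e1 = (p1 + length - 1) % n
    e2 = (p2 + length - 1) % n

    def covers(s, e, x):
        return s <= x <= e if s <= e else (x >= s or x <= e)

    return covers(p1, e1, p2) or covers(p2, e2, p1)


def brute_force_repeats(genome: CircularSequence, min_length: int,
                        orientations=("F", "P")) -> set[tuple]:
    """All maximal repeat pairs as (orientation, length, start1, start2)
    with 1-based starts, start1 < start2, overlapping copies excluded."""
    s = genome.sequence
    n = len(s)
    arr = np.frombuffer(s.encode(), np.uint8)
    found: set[tuple] = set()

    def record(orient: str, length: int, a: int, b: int) -> None:
        if length < min_length or length >= n:
            return
        p1, p2 = sorted((a % n, b % n))
        if p1 == p2 or _overlap(p1, p2, length, n):
            return
        found.add((orient, length, p1 + 1, p2 + 1))

    if "F" in orientations:
        for d in range(1, n // 2 + 1):
            eq = arr == np.roll(arr, -d)
            for a, length in _circular_runs(eq):
                record("F", length, a, a + d)
    if "P" in orientations:
        rarr = np.frombuffer(revcomp(s).encode(), np.uint8)
        for d in range(n):
            eq = arr == np.roll(rarr, -d)
            for a, length in _circular_runs(eq):
                x0 = (a + d) % n
                record("P", length, a, (n - x0 - length) % n)
    return found


def exhaustive_inversion_closure(mc: MoleculeState, max_depth: int = 6
                                 ) -> set[str]:
    """Canonical keys of every single circle reachable from ``mc`` by any
    sequence of up to ``max_depth`` inversion events (no pruning)."""
    reached: set[str] = set()

    def walk(state: MoleculeState, depth: int) -> None:
        reached.add(canonicalize(state))
        if depth == 0:
            return
        for pid in state.pair_ids():
            if pair_orientation(state, pid) == "inverted":
                (product,) = recombine(state, pid).products
                walk(product, depth - 1)

    walk(mc, max_depth)
    reached.discard(canonicalize(mc))
    return reached
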