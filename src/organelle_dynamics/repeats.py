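"""Maximal exact repeat pairs on circular genomes.

A repeat pair is two disjoint arcs of the genome whose sequences are
identical (forward, F) or reverse complements of each other (palindromic,
P), and which cannot be extended on either side without a mismatch.
Large palindromic pairs mediate isomerizing recombination of plant
mitochondrial master circles; forward pairs mediate excision into
subgenomic circles.

The finder is seed-and-extend: every k-mer of the circular sequence is
indexed, co-occurring k-mers define candidate diagonals, and each seed is
extended to the maximal matching run on its diagonal.  Circularity is
handled by modular indexing; a run covering the whole circle (the trivial
self-match of a rotation-periodic sequence) is discarded, as are pairs
whose two copies overlap on the circle.

The attached significance is the closed-form expectation
``E = orientations × N² × (1/4)^L`` of chance maximal pairs of length ≥ L
in an i.i.d. uniform sequence of length N.  It is reported for ranking
only; filtering is by ``min_length``, never by E-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .seqio import CircularSequence, revcomp

__all__ = ["RepeatPair", "RepeatConfig", "find_maximal_repeats", "repeat_evalue"]

logger = logging.getLogger(__name__)

#: formula reported in output metadata alongside every E-value
EVALUE_FORMULA = "E = orientations * N^2 * (1/4)^L"


@dataclass(frozen=True)
class RepeatPair:
    """A two-copy exact repeat.

    ``start1 < start2`` by convention (1-based positions of the two copy
    starts; each copy runs ``start..start+length-1`` circularly).  For
    orientation ``P`` the copy at ``start2`` is the reverse complement of
    the copy at ``start1``.
    """

    length: int
    start1: int
    start2: int
    orientation: str
    e_value: float | None = None

    def __post_init__(self) -> None:
        if self.orientation not in ("F", "P"):
            raise ValueError(f"orientation must be 'F' or 'P', got {self.orientation!r}")
        if self.length < 1:
            raise ValueError("repeat length must be positive")
        if self.start1 == self.start2:
            raise ValueError("the two copies must start at distinct positions")

    @property
    def pair_id(self) -> str:
        return f"r{self.length}@{self.start1}"

    def copy_intervals(self, n: int) -> list[tuple[int, int]]:
        """1-based inclusive (start, end) of both copies, end mod-wrapped."""
        out = []
        for s in (self.start1, self.start2):
            e = (s - 1 + self.length - 1) % n + 1
            out.append((s, e))
        return out

    def validate_on(self, genome: CircularSequence) -> bool:
        """Re-check the defining sequence identity on ``genome``."""
        (s1, e1), (s2, e2) = self.copy_intervals(genome.length)
        a = genome.fetch(s1, e1)
        b = genome.fetch(s2, e2)
        return a == b if self.orientation == "F" else a == revcomp(b)


@dataclass
class RepeatConfig:
    min_length: int = 50
    orientations: tuple[str, ...] = ("F", "P")
    max_pairs: int | None = None
    treat_circular: bool = True
    seed_length: int | None = field(default=None)

    def __post_init__(self) -> None:
        if self.min_length < 8:
            raise ValueError("min_length must be >= 8")
        bad = set(self.orientations) - {"F", "P"}
        if bad:
            raise ValueError(f"unknown orientations {sorted(bad)!r}")

    @property
    def k(self) -> int:
        return self.seed_length or min(self.min_length, 16)


def repeat_evalue(length: int, n: int, orientations: int = 2) -> float:
    """Expected number of chance maximal exact pairs of length >= ``length``
    in an i.i.d. uniform sequence of length ``n`` (monotone decreasing in
    ``length``; see ``EVALUE_FORMULA``)."""
    if length < 1 or n < length:
        raise ValueError("need 1 <= length <= n")
    return orientations * float(n) ** 2 * 0.25 ** length


def _overlap_circular(a: tuple[int, int], b: tuple[int, int], n: int) -> bool:
    """Whether two 1-based inclusive circular intervals share a base."""

    def covers(iv: tuple[int, int], p: int) -> bool:
        s, e = iv
        return s <= p <= e if s <= e else (p >= s or p <= e)

    return covers(a, b[0]) or covers(b, a[0])


class _DiagonalRuns:
    """Book-keeping of maximal runs already found per diagonal."""

    def __init__(self) -> None:
        self._runs: dict[int, list[tuple[int, int]]] = {}

    def seen(self, d: int, pos: int) -> bool:
        for a, length in self._runs.get(d, ()):  # runs per diagonal are few
            if a <= pos < a + length:
                return True
        return False

    def add(self, d: int, a: int, length: int) -> None:
        self._runs.setdefault(d, []).append((a, length))


def _extend_run(match, i: int, limit: int) -> tuple[int, int]:
    """Maximal run of True values of ``match`` containing ``i``.

    Returns (start, length); length is capped at ``limit`` (a run reaching
    the cap means the whole circle matches on this diagonal).
    """
    left = i
    while i - left < limit and match(left - 1):
        left -= 1
    right = i
    while right - left + 1 < limit + 1 and match(right + 1):
        right += 1
    return left, right - left + 1


def find_maximal_repeats(genome: CircularSequence,
                         config: RepeatConfig | None = None) -> list[RepeatPair]:
    """All maximal exact repeat pairs >= ``config.min_length``.

    Pairs are sorted by decreasing length, ties by ``start1``.  On genomes
    shorter than ``2 * min_length`` an empty list is returned with a
    warning.
    """
    config = config or RepeatConfig()
    s = genome.sequence
    n = len(s)
    if n < 2 * config.min_length:
        logger.warning("genome %s (%d bp) shorter than 2*min_length=%d; "
                       "no repeats reported", genome.id, n, 2 * config.min_length)
        return []
    circular = config.treat_circular and genome.is_circular
    k = config.k
    n_orient = len(set(config.orientations))
    found: dict[tuple, RepeatPair] = {}

    def index_kmers(t: str) -> dict[str, list[int]]:
        idx: dict[str, list[int]] = {}
        tt = t + t[: k - 1] if circular else t
        top = n if circular else n - k + 1
        for i in range(top):
            idx.setdefault(tt[i : i + k], []).append(i)
        return idx

    def record(length: int, a0: int, b0: int, orientation: str) -> None:
        # a0/b0 are 0-based copy starts (mod n); canonicalize start1 < start2
        p1, p2 = sorted(((a0 % n) + 1, (b0 % n) + 1))
        iv1 = (p1, (p1 - 1 + length - 1) % n + 1)
        iv2 = (p2, (p2 - 1 + length - 1) % n + 1)
        if _overlap_circular(iv1, iv2, n):
            return
        key = (length, p1, p2, orientation)
        if key not in found:
            found[key] = RepeatPair(length, p1, p2, orientation,
                                    repeat_evalue(length, n, n_orient))

    if "F" in config.orientations:
        idx = index_kmers(s)
        runs = _DiagonalRuns()

        def fmatch(d):
            if circular:
                return lambda p: s[p % n] == s[(p + d) % n]
            return lambda p: 0 <= p and p + d < n and s[p] == s[p + d]

        for positions in idx.values():
            if len(positions) < 2:
                continue
            for ii, i in enumerate(positions):
                for j in positions[ii + 1 :]:
                    d = (j - i) % n if circular else j - i
                    if d == 0 or runs.seen(d, i):
                        continue
                    a, length = _extend_run(fmatch(d), i, n)
                    runs.add(d, a, length)
                    if length >= n:  # trivial self-match of the circle
                        continue
                    if length >= config.min_length:
                        record(length, a, a + d, "F")

    if "P" in config.orientations:
        r = revcomp(s)
        ridx = index_kmers(r)
        sidx = index_kmers(s)
        runs = _DiagonalRuns()

        def pmatch(d):
            if circular:
                return lambda p: s[p % n] == r[(p + d) % n]
            return lambda p: 0 <= p and 0 <= p + d < n and s[p] == r[p + d]

        for kmer, positions in sidx.items():
            for q in ridx.get(kmer, ()):  # s k-mer at i matches r k-mer at q
                for i in positions:
                    d = (q - i) % n if circular else q - i
                    if runs.seen(d, i):
                        continue
                    a, length = _extend_run(pmatch(d), i, n)
                    runs.add(d, a, length)
                    if length >= n:
                        continue
                    if length >= config.min_length:
                        # map r-interval back to an s-copy start
                        x0 = (a + d) % n if circular else a + d
                        b0 = (n - x0 - length) % n
                        record(length, a, b0, "P")

    out = sorted(found.values(), key=lambda p: (-p.length, p.start1, p.start2))
    if config.max_pairs is not None:
        out = out[: config.max_pairs]
    return out
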