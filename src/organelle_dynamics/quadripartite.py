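"""Quadripartite architecture of chloroplast genomes.

Most land-plant chloroplast genomes carry two large inverted repeats (IRa
and IRb, exact reverse complements here) separating a large and a small
single-copy region (LSC, SSC).  The detector reuses the maximal-repeat
finder: the longest palindromic pair at least ``min_ir`` long defines the
IRs, and the two inter-IR arcs are assigned LSC (longer) and SSC
(shorter).  Region lengths always satisfy ``2*IR + LSC + SSC = N``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .repeats import RepeatConfig, find_maximal_repeats
from .seqio import CircularSequence, GenomeFeature, arc_interval

__all__ = ["QuadripartiteMap", "detect_quadripartite", "junction_features"]

JUNCTIONS = ("LSC/IRa", "IRa/SSC", "SSC/IRb", "IRb/LSC")


@dataclass(frozen=True)
class QuadripartiteMap:
    """IRa/IRb/LSC/SSC intervals (1-based inclusive, possibly wrapping)."""

    ira: tuple[int, int]
    irb: tuple[int, int]
    lsc: tuple[int, int]
    ssc: tuple[int, int]
    n: int

    @property
    def ir_length(self) -> int:
        return arc_interval(*self.ira, self.n)

    @property
    def lsc_length(self) -> int:
        return arc_interval(*self.lsc, self.n)

    @property
    def ssc_length(self) -> int:
        return arc_interval(*self.ssc, self.n)

    def fractions(self) -> dict[str, float]:
        """Genome fraction per region; the IR fraction is per single copy."""
        return {
            "IR": self.ir_length / self.n,
            "LSC": self.lsc_length / self.n,
            "SSC": self.ssc_length / self.n,
        }

    def region_of(self, pos: int) -> str:
        """Region (LSC/SSC/IR) containing a 1-based position."""
        for name, iv in (("LSC", self.lsc), ("SSC", self.ssc),
                         ("IR", self.ira), ("IR", self.irb)):
            s, e = iv
            if (s <= pos <= e) if s <= e else (pos >= s or pos <= e):
                return name
        raise ValueError(f"position {pos} outside [1, {self.n}]")

    def junctions(self) -> dict[str, int]:
        """Junction name -> last base of the upstream region."""
        return {
            "LSC/IRa": self.lsc[1],
            "IRa/SSC": self.ira[1],
            "SSC/IRb": self.ssc[1],
            "IRb/LSC": self.irb[1],
        }


def detect_quadripartite(genome: CircularSequence, min_ir: int = 1000
                         ) -> QuadripartiteMap | None:
    """Detect IRa/IRb/LSC/SSC; ``None`` when no palindromic pair >= min_ir.

    Raises on a tie between non-identical candidate pairs of equal maximal
    length (manual choice required).
    """
    pairs = find_maximal_repeats(
        genome, RepeatConfig(min_length=max(min_ir, 8), orientations=("P",))
    )
    if not pairs:
        return None
    best = pairs[0]
    ties = [p for p in pairs if p.length == best.length]
    if len(ties) > 1:
        raise ValueError(
            f"{len(ties)} palindromic pairs of maximal length {best.length}; "
            "IR assignment requires a manual choice"
        )
    n = genome.length
    (s1, e1), (s2, e2) = best.copy_intervals(n)
    gap_a = (s2 - e1 - 1) % n  # arc e1+1 .. s2-1
    gap_b = (s1 - e2 - 1) % n  # arc e2+1 .. s1-1
    arc_a = ((e1 % n) + 1, (s2 - 2) % n + 1)
    arc_b = ((e2 % n) + 1, (s1 - 2) % n + 1)
    if gap_a == 0 or gap_b == 0:
        return None  # IR copies adjacent: no quadripartite structure
    if gap_a >= gap_b:
        lsc, ssc = arc_a, arc_b
        ira, irb = (s1, e1), (s2, e2)
    else:
        lsc, ssc = arc_b, arc_a
        # keep the convention LSC -> IRa -> SSC -> IRb around the circle
        ira, irb = (s2, e2), (s1, e1)
    qmap = QuadripartiteMap(ira=ira, irb=irb, lsc=lsc, ssc=ssc, n=n)
    assert 2 * qmap.ir_length + qmap.lsc_length + qmap.ssc_length == n
    return qmap


def junction_features(qmap: QuadripartiteMap, features: list[GenomeFeature]
                      ) -> dict[str, list[tuple[GenomeFeature, str]]]:
    """Features containing or abutting each of the four junction bases.

    A junction sits between the last base of the upstream region and the
    first base of the downstream one; a feature *contains* the junction if
    it covers both flanking bases and *abuts* it if it ends or starts
    exactly at it.
    """
    n = qmap.n
    out: dict[str, list[tuple[GenomeFeature, str]]] = {j: [] for j in JUNCTIONS}
    for jname, last in qmap.junctions().items():
        first = last % n + 1
        for f in features:
            covers_last = f.contains(last, n)
            covers_first = f.contains(first, n)
            if covers_last and covers_first:
                out[jname].append((f, "contains"))
            elif covers_last or covers_first:
                out[jname].append((f, "abuts"))
    return out
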