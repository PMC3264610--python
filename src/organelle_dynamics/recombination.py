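"""Repeat-mediated recombination of a circular master molecule.

A master circle (MC) carrying a set of disjoint two-copy repeats is
decomposed into the inter-repeat *segments* (labelled A, B, ... from the
lowest-coordinate segment start).  A molecule is then an abstract cyclic
arrangement of signed units — segments and repeat copies — and
intra-molecular recombination across a repeat pair rewrites that
arrangement:

* **inverted pair** (copies on opposite strands): the arc strictly between
  the two copies is reversed and strand-flipped, yielding one *isomeric*
  circle with the same segment content;
* **direct pair** (copies on the same strand): the circle is excised into
  two *subgenomic* circles, each retaining one repeat copy.

Isomer enumeration is a breadth-first closure: starting from the MC,
recombination is applied at every currently inverted pair of every reached
single-circle state until no new canonical state appears.  Excision
products are recorded but not expanded.  States are compared after
canonicalization under rotation and whole-molecule strand flip, so the two
possible arcs of an inversion yield the same molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .repeats import RepeatPair
from .seqio import GenomeFeature, arc_interval

__all__ = [
    "Segment",
    "Unit",
    "MoleculeState",
    "RecombinationOutcome",
    "decompose_segments",
    "build_master_state",
    "pair_orientation",
    "recombine",
    "enumerate_isomers",
    "canonicalize",
    "molecule_gene_report",
]

_LABELS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class Segment:
    """One inter-repeat arc of the master circle."""

    label: str
    start: int
    end: int
    printed_length: int
    inclusive_length: int


@dataclass(frozen=True)
class Unit:
    """One signed unit of a molecule: a segment or a repeat copy."""

    kind: str  # "seg" | "rep"
    name: str  # segment label or repeat pair id
    sign: int  # +1 | -1

    def flipped(self) -> "Unit":
        return replace(self, sign=-self.sign)

    def token(self) -> str:
        return f"{self.name}{'+' if self.sign > 0 else '-'}"


@dataclass(frozen=True)
class MoleculeState:
    """A circular signed arrangement of units."""

    units: tuple[Unit, ...]
    provenance: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.units)

    def segment_multiset(self) -> tuple[str, ...]:
        return tuple(sorted(u.name for u in self.units if u.kind == "seg"))

    def pair_ids(self) -> list[str]:
        seen = []
        for u in self.units:
            if u.kind == "rep" and u.name not in seen:
                seen.append(u.name)
        return seen

    def key(self) -> str:
        return canonicalize(self)


@dataclass(frozen=True)
class RecombinationOutcome:
    kind: str  # "isomer" | "excision"
    products: tuple[MoleculeState, ...]


def _check_disjoint(pairs: list[RepeatPair], n: int) -> list[tuple[int, int, str]]:
    """All repeat-copy intervals in circular order; error on any collision."""
    copies: list[tuple[int, int, str]] = []  # (start, end, pair_id) 1-based
    for p in pairs:
        for s, e in p.copy_intervals(n):
            copies.append((s, e, p.pair_id))
    copies.sort()
    m = len(copies)
    for i in range(m):
        s1, e1, id1 = copies[i]
        s2, e2, id2 = copies[(i + 1) % m]
        span1 = arc_interval(s1, e1, n, "inclusive")
        # the next copy (circularly) must start past the end of this one
        if m > 1 and (s2 - s1) % n < span1 and (s1, e1) != (s2, e2):
            raise ValueError(
                f"repeat copies overlap: {id1} ({s1}..{e1}) and {id2} ({s2}..{e2})"
            )
    return copies


def decompose_segments(n: int, pairs: list[RepeatPair]) -> list[Segment]:
    """Inter-repeat segments of a circle of length ``n``.

    One segment per gap between consecutive repeat copies in circular
    order; labels run A, B, ... from the segment with the smallest start
    coordinate.  With no pairs, a single segment covers the circle.
    """
    if not pairs:
        return [Segment("A", 1, n, n - 1, n)]
    copies = _check_disjoint(pairs, n)
    raw: list[tuple[int, int]] = []
    m = len(copies)
    for i in range(m):
        _, e1, _ = copies[i]
        s2, _, _ = copies[(i + 1) % m]
        start = e1 % n + 1
        end = (s2 - 2) % n + 1
        gap = (s2 - 1 - e1) % n
        if gap == 0:  # adjacent copies: empty segment
            continue
        raw.append((start, end))
    raw.sort()
    segs = []
    for label, (start, end) in zip(_LABELS, raw):
        segs.append(
            Segment(label, start, end,
                    printed_length=arc_interval(start, end, n, "printed"),
                    inclusive_length=arc_interval(start, end, n, "inclusive"))
        )
    if len(raw) > len(_LABELS):
        raise ValueError("more segments than available labels")
    # tiling invariant: segments plus both copies of every pair cover n
    total = sum(s.inclusive_length for s in segs) + sum(2 * p.length for p in pairs)
    if total != n:
        raise AssertionError(
            f"decomposition does not tile the circle: {total} != {n}"
        )
    return segs


def build_master_state(segments: list[Segment], pairs: list[RepeatPair],
                       n: int | None = None) -> MoleculeState:
    """The MC as a unit cycle in genomic order.

    All strands are ``+`` except the second copy of each palindromic pair,
    which is the reverse complement of the first and carries ``-``.
    """
    if n is None:
        n = sum(s.inclusive_length for s in segments) + sum(2 * p.length for p in pairs)
    items: list[tuple[int, Unit]] = []
    for seg in segments:
        items.append((seg.start, Unit("seg", seg.label, +1)))
    for p in pairs:
        sign2 = -1 if p.orientation == "P" else +1
        items.append((p.start1, Unit("rep", p.pair_id, +1)))
        items.append((p.start2, Unit("rep", p.pair_id, sign2)))
    items.sort(key=lambda t: t[0])
    state = MoleculeState(tuple(u for _, u in items), provenance=("MC",))
    for pid in state.pair_ids():
        if sum(1 for u in state.units if u.kind == "rep" and u.name == pid) != 2:
            raise ValueError(f"pair {pid} does not occur exactly twice")
    return state


def _pair_indices(state: MoleculeState, pair_id: str) -> tuple[int, int]:
    idx = [i for i, u in enumerate(state.units)
           if u.kind == "rep" and u.name == pair_id]
    if len(idx) != 2:
        raise ValueError(f"pair {pair_id!r} must occur exactly twice in the "
                         f"molecule (found {len(idx)})")
    return idx[0], idx[1]


def pair_orientation(state: MoleculeState, pair_id: str) -> str:
    """``inverted`` if the two copies have opposite signs, else ``direct``."""
    i, j = _pair_indices(state, pair_id)
    return "inverted" if state.units[i].sign != state.units[j].sign else "direct"


def recombine(state: MoleculeState, pair_id: str) -> RecombinationOutcome:
    """Apply intra-molecular recombination at ``pair_id``.

    Inverted pair -> one isomer (the arc between the copies reversed and
    strand-flipped); direct pair -> two excision circles, each keeping one
    repeat copy.
    """
    i, j = _pair_indices(state, pair_id)
    units = state.units
    event = f"recombine:{pair_id}"
    if pair_orientation(state, pair_id) == "inverted":
        arc = tuple(u.flipped() for u in reversed(units[i + 1 : j]))
        new = units[: i + 1] + arc + units[j:]
        return RecombinationOutcome(
            "isomer", (MoleculeState(new, state.provenance + (event,)),)
        )
    circle1 = (units[i],) + units[i + 1 : j]
    circle2 = (units[j],) + units[j + 1 :] + units[:i]
    return RecombinationOutcome(
        "excision",
        (MoleculeState(circle1, state.provenance + (event, "excised:1")),
         MoleculeState(circle2, state.provenance + (event, "excised:2"))),
    )


def canonicalize(state: MoleculeState) -> str:
    """Unique text key under rotation and whole-molecule strand flip."""
    tokens = [u.token() for u in state.units]
    flipped = [u.flipped().token() for u in reversed(state.units)]
    best = None
    for seq in (tokens, flipped):
        m = len(seq)
        for r in range(m):
            cand = " ".join(seq[r:] + seq[:r])
            if best is None or cand < best:
                best = cand
    return best or ""


def enumerate_isomers(mc: MoleculeState, max_states: int = 10_000
                      ) -> tuple[dict[str, MoleculeState], list[RecombinationOutcome]]:
    """Breadth-first closure of inversion events from the MC.

    Returns ``(isomers, excisions)``: canonical-key -> state for every
    reachable single circle other than the MC itself, plus the excision
    outcomes encountered along the way (recorded, not expanded).
    """
    mc_key = canonicalize(mc)
    seen: dict[str, MoleculeState] = {mc_key: mc}
    excisions: list[RecombinationOutcome] = []
    excision_keys: set[tuple[str, ...]] = set()
    frontier = [mc]
    while frontier:
        nxt: list[MoleculeState] = []
        for state in frontier:
            for pid in state.pair_ids():
                if pair_orientation(state, pid) == "inverted":
                    (product,) = recombine(state, pid).products
                    key = canonicalize(product)
                    if key not in seen:
                        seen[key] = product
                        nxt.append(product)
                else:
                    out = recombine(state, pid)
                    sig = tuple(sorted(canonicalize(p) for p in out.products))
                    if sig not in excision_keys:
                        excision_keys.add(sig)
                        excisions.append(out)
        frontier = nxt
        if len(seen) > max_states:
            raise RuntimeError("state space exceeds max_states")
    isomers = {k: v for k, v in seen.items() if k != mc_key}
    return isomers, excisions


def molecule_gene_report(state: MoleculeState, features: list[GenomeFeature],
                         segments: list[Segment], pairs: list[RepeatPair],
                         n: int) -> dict[str, dict]:
    """Per-gene exon strand patterns in a (possibly rearranged) molecule.

    Each exon feature must lie wholly within one segment or one repeat
    copy of the master circle.  In ``state``, an exon's strand is its
    annotated strand composed with the sign its host unit carries; the
    pattern string lists exon strands in exon order.  Genes with exons on
    both strands are flagged cross-strand; exons hosted by units absent
    from ``state`` (e.g. after excision) are flagged missing and shown as
    ``.`` in the pattern.
    """
    unit_sign = {}
    for u in state.units:
        unit_sign[(u.kind, u.name)] = u.sign

    def host_of(f: GenomeFeature) -> tuple[str, str]:
        for seg in segments:
            if _within(f, seg.start, seg.end, n):
                return ("seg", seg.label)
        for p in pairs:
            for s, e in p.copy_intervals(n):
                if _within(f, s, e, n):
                    return ("rep", p.pair_id)
        raise ValueError(
            f"exon {f.name!r} ({f.start}..{f.end}) spans a segment boundary"
        )

    genes: dict[str, list[GenomeFeature]] = {}
    for f in features:
        if f.kind == "exon":
            genes.setdefault(f.name, []).append(f)
    report: dict[str, dict] = {}
    for gene, exons in genes.items():
        exons = sorted(exons, key=lambda f: (f.exon_index or 0))
        pattern = []
        missing = []
        for f in exons:
            host = host_of(f)
            if host not in unit_sign:
                pattern.append(".")
                missing.append(f.exon_index)
                continue
            sign = unit_sign[host] * (1 if f.strand == "+" else -1)
            pattern.append("+" if sign > 0 else "-")
        pat = "".join(pattern)
        report[gene] = {
            "pattern": pat,
            "cross_strand": "+" in pat and "-" in pat,
            "missing_exons": missing,
        }
    return report


def _within(f: GenomeFeature, start: int, end: int, n: int) -> bool:
    """Whether feature arc lies wholly inside the arc ``start..end``."""
    off_s = (f.start - start) % n
    off_e = (f.end - start) % n
    span = (end - start) % n
    return off_s <= off_e <= span
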