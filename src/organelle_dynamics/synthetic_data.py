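"""Synthetic circular genomes with known ground truth.

Every detector in the package is exercised against genomes built here:
i.i.d. background sequence at a controlled GC with planted, exactly known
structure — repeat pairs (forward or palindromic), a quadripartite
chloroplast layout, chloroplast-derived insertions mutated to an exact
nucleotide identity, and tRNA gene sets of mixed native/cp-copied origin.

The mutation model is substitution-only by default (exactly
``round((1-identity) * length)`` substitutions at uniformly drawn distinct
positions, never back to the original base), so planted identities are
exact and recall/precision checks are deterministic under a seed.  An
indel-enabled mode exists for robustness tests only.  All randomness goes
through ``numpy.random.default_rng`` (PCG64), so a seed pins every output
across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .quadripartite import QuadripartiteMap
from .repeats import RepeatPair
from .seqio import AnnotatedGenome, CircularSequence, GenomeFeature, revcomp
from .transfer import InsertionHit

__all__ = [
    "SimScenario",
    "random_sequence",
    "mutate_to_identity",
    "simulate_repeat_genome",
    "simulate_quadripartite_genome",
    "simulate_transfer_pair",
    "simulate_trna_sets",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimScenario:
    """Parameters of one simulation.

    ``planted_repeats`` entries are (length, pos1, pos2, orientation);
    ``quadripartite`` is (lsc, ir, ssc) lengths; ``planted_insertions``
    entries are (cp_start, length, identity, mt_pos, strand).  All
    positions 1-based.  Defaults reflect the scale of a plant organellar
    study: a cp-like genome of ~15 kb (scaled down from ~150 kb), an
    mt-like genome of ~60 kb (scaled down from ~510 kb), cp background GC
    0.38 and mt background GC 0.43.
    """

    seed: int = 0
    length: int = 60_000
    gc: float = 0.43
    planted_repeats: list = field(default_factory=list)
    quadripartite: tuple[int, int, int] | None = None
    planted_insertions: list = field(default_factory=list)
    cp_length: int = 15_000
    cp_gc: float = 0.38
    n_native_trnas: int = 6
    n_cp_trnas: int = 4
    trna_mutation_rate: float = 0.02

    def __post_init__(self) -> None:
        for entry in self.planted_insertions:
            identity = entry[2]
            if not (0.5 <= identity <= 1.0):
                raise ValueError(
                    f"planted identity {identity} outside the model range "
                    "[0.5, 1.0]")


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """i.i.d. background with the requested GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def mutate_to_identity(seq: str, identity: float,
                       rng: np.random.Generator | int,
                       indel_rate: float = 0.0) -> str:
    """Substitute exactly ``round((1-identity)*len)`` positions.

    Substituted bases are drawn uniformly from the three non-original
    bases, so the Hamming distance to the input is exact.  ``indel_rate``
    > 0 additionally applies single-base insertions/deletions (robustness
    testing only; identities are then approximate).
    """
    if not (0.5 <= identity <= 1.0):
        raise ValueError("identity must be in [0.5, 1.0]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n_sub = round((1.0 - identity) * len(seq))
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    if n_sub:
        pos = rng.choice(len(seq), size=n_sub, replace=False)
        for p in pos:
            choices = _BASES[_BASES != arr[p]]
            arr[p] = rng.choice(choices)
    out = arr.tobytes().decode()
    if indel_rate > 0:
        chars = list(out)
        i = 0
        while i < len(chars):
            r = rng.random()
            if r < indel_rate / 2:
                del chars[i]
            elif r < indel_rate:
                chars.insert(i, str(rng.choice(_BASES), "ascii"))
                i += 2
            else:
                i += 1
        out = "".join(chars)
    return out


def _plant(seq: list[str], block: str, pos: int, circular: bool = False) -> None:
    """Overwrite ``seq`` (0-based char list) with ``block`` at 1-based pos."""
    n = len(seq)
    if pos - 1 + len(block) > n:
        if not circular:
            raise ValueError("planted element does not fit in the genome")
        for off, ch in enumerate(block):
            seq[(pos - 1 + off) % n] = ch
        return
    seq[pos - 1 : pos - 1 + len(block)] = list(block)


def _check_no_overlap(intervals: list[tuple[int, int]], n: int | None = None) -> None:
    """Planted intervals must be pairwise disjoint (circularly when ``n``
    is given); exact duplicates (a shared source block) are allowed."""
    unique = sorted(set(intervals))
    covered: set[int] = set()
    for s, e in unique:
        span = (range(s, e + 1) if n is None
                else [(p - 1) % n + 1 for p in range(s, e + 1)])
        if covered.intersection(span):
            raise ValueError(f"planted elements overlap at {s}..{e}")
        covered.update(span)


def simulate_repeat_genome(scenario: SimScenario
                           ) -> tuple[CircularSequence, list[RepeatPair]]:
    """Background genome with planted exact repeat pairs.

    Each (length, pos1, pos2, orientation) entry copies the block at
    ``pos1`` to ``pos2`` verbatim (F) or as its reverse complement (P).
    Returns the genome and the truth table of planted pairs.
    """
    rng = np.random.default_rng(scenario.seed)
    chars = list(random_sequence(rng, scenario.length, scenario.gc))
    intervals = []
    for length, pos1, pos2, _ in scenario.planted_repeats:
        intervals += [(pos1, pos1 + length - 1), (pos2, pos2 + length - 1)]
    _check_no_overlap(intervals, n=scenario.length)
    truth = []
    n = scenario.length
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def differ(i: int, j: int, complementary: bool) -> None:
        # force a mismatch at the flank so the planted length is maximal
        ref = comp[chars[i]] if complementary else chars[i]
        if chars[j] == ref:
            chars[j] = str(rng.choice(_BASES[_BASES != ref.encode()]), "ascii")

    for length, pos1, pos2, orientation in scenario.planted_repeats:
        block = "".join(chars[(pos1 - 1 + off) % n] for off in range(length))
        _plant(chars, revcomp(block) if orientation == "P" else block, pos2,
               circular=True)
        a, b = pos1 - 1, pos2 - 1  # 0-based copy starts
        if orientation == "F":
            differ((a - 1) % n, (b - 1) % n, False)
            differ((a + length) % n, (b + length) % n, False)
        else:
            differ((a - 1) % n, (b + length) % n, True)
            differ((a + length) % n, (b - 1) % n, True)
        s1, s2 = sorted((pos1, pos2))
        truth.append(RepeatPair(length, s1, s2, orientation))
    genome = CircularSequence(f"sim_repeat_{scenario.seed}", "".join(chars))
    return genome, truth


def simulate_quadripartite_genome(scenario: SimScenario
                                  ) -> tuple[CircularSequence, QuadripartiteMap]:
    """cp-like genome LSC + IRa + SSC + IRb with IRb = revcomp(IRa)."""
    if scenario.quadripartite is None:
        raise ValueError("scenario.quadripartite not set")
    lsc, ir, ssc = scenario.quadripartite
    rng = np.random.default_rng(scenario.seed)
    lsc_seq = list(random_sequence(rng, lsc, scenario.cp_gc))
    ira = random_sequence(rng, ir, scenario.cp_gc)
    ssc_seq = list(random_sequence(rng, ssc, scenario.cp_gc))
    # break chance palindromic extension at the four junctions so the
    # planted IR length is exactly maximal: the base before IRa must not
    # pair with the base after IRb (first LSC base), and the base after
    # IRa (first SSC base) must not pair with the base before IRb (last
    # SSC base)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    while lsc_seq[-1] == comp[lsc_seq[0]]:
        lsc_seq[-1] = str(rng.choice(_BASES), "ascii")
    while ssc_seq[0] == comp[ssc_seq[-1]]:
        ssc_seq[0] = str(rng.choice(_BASES), "ascii")
    seq = "".join(lsc_seq) + ira + "".join(ssc_seq) + revcomp(ira)
    n = len(seq)
    qmap = QuadripartiteMap(
        ira=(lsc + 1, lsc + ir),
        irb=(lsc + ir + ssc + 1, n),
        lsc=(1, lsc),
        ssc=(lsc + ir + 1, lsc + ir + ssc),
        n=n,
    )
    return CircularSequence(f"sim_cp_{scenario.seed}", seq), qmap


def simulate_transfer_pair(scenario: SimScenario
                           ) -> tuple[AnnotatedGenome, AnnotatedGenome,
                                      QuadripartiteMap, list[InsertionHit]]:
    """mt-like genome carrying cp-derived insertions, plus its cp genome.

    The cp genome gets a quadripartite layout (default roughly the
    LSC:IR:SSC proportions of an angiosperm plastome scaled to
    ``cp_length``).  Each (cp_start, length, identity, mt_pos, strand)
    entry copies a cp block, mutates it to the exact identity, and
    overwrites the mt background at ``mt_pos``.  The truth list records
    planted intervals, identities and cp region of origin.
    """
    rng = np.random.default_rng(scenario.seed)
    if scenario.quadripartite is not None:
        lsc, ir, ssc = scenario.quadripartite
    else:
        n = scenario.cp_length
        lsc, ir, ssc = round(n * 0.55), round(n * 0.166), 0
        ssc = n - lsc - 2 * ir
    cp_scn = SimScenario(seed=scenario.seed + 1, quadripartite=(lsc, ir, ssc),
                         cp_gc=scenario.cp_gc)
    cp_seq, qmap = simulate_quadripartite_genome(cp_scn)
    mt_chars = list(random_sequence(rng, scenario.length, scenario.gc))
    _check_no_overlap(
        [(p[3], p[3] + p[1] - 1) for p in scenario.planted_insertions])
    truth = []
    from .seqio import gc_content  # local import to avoid cycle at module load

    for cp_start, length, identity, mt_pos, strand in scenario.planted_insertions:
        block = cp_seq.fetch(cp_start, (cp_start - 1 + length - 1) % cp_seq.length + 1)
        if strand == "-":
            block = revcomp(block)
        mutated = mutate_to_identity(block, identity, rng)
        _plant(mt_chars, mutated, mt_pos)
        mid = (cp_start + length // 2 - 1) % cp_seq.length + 1
        truth.append(InsertionHit(
            mt_interval=(mt_pos, mt_pos + length - 1),
            cp_interval=(cp_start, (cp_start - 1 + length - 1) % cp_seq.length + 1),
            strand=strand,
            identity=identity,
            aligned_length=length,
            score=0,
            e_value=0.0,
            gc=gc_content(mutated),
            cp_region=qmap.region_of(mid),
        ))
    mt = AnnotatedGenome(CircularSequence(f"sim_mt_{scenario.seed}",
                                          "".join(mt_chars)))
    cp = AnnotatedGenome(cp_seq)
    return mt, cp, qmap, truth


#: a compact, realistic tRNA-sized alphabet soup is enough for identity
#: classification tests; real cloverleaf structure is irrelevant here.
def simulate_trna_sets(scenario: SimScenario
                       ) -> tuple[list[tuple[str, str]], list[tuple[str, str]],
                                  dict[str, str]]:
    """(mt_trnas, cp_trnas, truth) with truth mapping mt tRNA name ->
    'native' | 'cp-derived'.

    cp tRNAs are independent random ~75-nt sequences; ``n_cp_trnas`` of
    the mt set are copies of cp tRNAs mutated at ``trna_mutation_rate``,
    the rest are independent (native).
    """
    rng = np.random.default_rng(scenario.seed)
    cp_trnas = [(f"cp-trn{i}", random_sequence(rng, int(rng.integers(70, 90)),
                                               0.5))
                for i in range(max(scenario.n_cp_trnas, 8))]
    mt_trnas = []
    truth = {}
    for i in range(scenario.n_native_trnas):
        name = f"mt-native{i}"
        mt_trnas.append((name, random_sequence(rng, int(rng.integers(70, 90)),
                                               0.5)))
        truth[name] = "native"
    for i in range(scenario.n_cp_trnas):
        name = f"mt-cpcopy{i}"
        src = cp_trnas[i][1]
        ident = 1.0 - scenario.trna_mutation_rate
        mt_trnas.append((name, mutate_to_identity(src, ident, rng)))
        truth[name] = "cp-derived"
    order = rng.permutation(len(mt_trnas))
    mt_trnas = [mt_trnas[i] for i in order]
    return mt_trnas, cp_trnas, truth
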