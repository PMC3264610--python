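"""Codon usage and anticodon-based decodability.

A chloroplast genome typically carries ~30 tRNA genes yet must read all 61
sense codons; the shortfall is covered by relaxed pairing at codon
position 3 / anticodon position 34 (the "wobble" position).  The rule set
implemented here, from permissive to strict:

* ``strict``  — classic wobble only: G34 reads C and U; U34 reads A and G;
  C34 reads G; A34 reads U.
* ``superwobble`` — additionally, a U34 tRNA serving a *family box* (a
  four-codon box encoding one amino acid) reads all four codons of the box.
* ``two_out_of_three`` — additionally, any tRNA serving a family box that
  has no U34 isoacceptor unlocks the whole box (pairing at the first two
  codon positions suffices).

A special case is the lysidine-type modification of C34 in trnI-CAU,
which lets it read AUA (Ile) in addition to AUG; it is on by default and
applies only to tRNAs named ``trnI-CAU``.

Decoded-codon sets are monotone in the policy:
strict ⊆ superwobble ⊆ two_out_of_three.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

from Bio.Data import CodonTable as _BioCodonTable

__all__ = ["CodonTable", "WobbleRuleSet", "codon_usage", "decodable_codons",
           "STOP_CODONS", "SENSE_CODONS", "FAMILY_BOX_PREFIXES"]

logger = logging.getLogger(__name__)

_RNA = "UCAG"
_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: plastid/bacterial genetic code (NCBI table 11) on RNA codons
_CODE11 = _BioCodonTable.unambiguous_rna_by_id[11]
STOP_CODONS = tuple(sorted(_CODE11.stop_codons))  # UAA, UAG, UGA
ALL_CODONS = tuple("".join(c) for c in product(_RNA, repeat=3))
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)

#: the eight four-codon family boxes of the standard/plastid code
FAMILY_BOX_PREFIXES = tuple(
    sorted({c[:2] for c in SENSE_CODONS
            if all(p + b in _CODE11.forward_table
                   and _CODE11.forward_table[p + b] == _CODE11.forward_table[c]
                   for p in [c[:2]] for b in _RNA)})
)


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass
class CodonTable:
    """Frame-0 codon counts plus terminal stop-codon fractions."""

    counts: dict[str, int]
    stop_fractions: dict[str, float]  # percent per stop codon
    n_cds: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonTable") -> "CodonTable":
        counts = {c: self.counts.get(c, 0) + other.counts.get(c, 0)
                  for c in ALL_CODONS}
        n_stops = {s: round(self.stop_fractions.get(s, 0) * self.n_cds
                            + other.stop_fractions.get(s, 0) * other.n_cds)
                   for s in STOP_CODONS}
        tot = sum(n_stops.values())
        fr = {s: 100.0 * v / tot if tot else 0.0 for s, v in n_stops.items()}
        return CodonTable(counts, fr, self.n_cds + other.n_cds)


def codon_usage(cds_sequences: list[str], genetic_code: int = 11) -> CodonTable:
    """Codon counts over a CDS set (DNA or RNA input; tables are in RNA).

    Trailing bases of a CDS whose length is not a multiple of 3 are
    dropped with a warning; internal stop codons are warned about (a
    common signature of RNA editing in organellar genes) but counted.
    Stop fractions are computed over terminal codons only.
    """
    code = _BioCodonTable.unambiguous_rna_by_id[genetic_code]
    counts = {c: 0 for c in ALL_CODONS}
    stop_counts = {s: 0 for s in code.stop_codons}
    n_terminal = 0
    for i, cds in enumerate(cds_sequences):
        seq = _rna(cds)
        if len(seq) % 3:
            logger.warning("CDS %d length %d not a multiple of 3; dropping "
                           "%d trailing bases", i, len(seq), len(seq) % 3)
            seq = seq[: len(seq) - len(seq) % 3]
        codons = [seq[j : j + 3] for j in range(0, len(seq), 3)]
        for pos, codon in enumerate(codons):
            if codon in counts:
                counts[codon] += 1
            if codon in stop_counts and pos < len(codons) - 1:
                logger.warning("internal stop %s at codon %d of CDS %d "
                               "(possible RNA editing site)", codon, pos + 1, i)
        if codons and codons[-1] in stop_counts:
            stop_counts[codons[-1]] += 1
            n_terminal += 1
    fractions = {s: (100.0 * v / n_terminal if n_terminal else 0.0)
                 for s, v in stop_counts.items()}
    return CodonTable(counts, fractions, len(cds_sequences))


@dataclass
class WobbleRuleSet:
    """Anticodon-34 pairing policy.

    ``policy`` is one of ``strict``, ``superwobble``,
    ``two_out_of_three``; ``lysidine_cau`` enables AUA decoding by
    trnI-CAU.
    """

    policy: str = "two_out_of_three"
    lysidine_cau: bool = True

    _ORDER = ("strict", "superwobble", "two_out_of_three")

    def __post_init__(self) -> None:
        if self.policy not in self._ORDER:
            raise ValueError(f"unknown policy {self.policy!r}")

    def at_least(self, policy: str) -> bool:
        return self._ORDER.index(self.policy) >= self._ORDER.index(policy)


#: classic wobble pairing of anticodon position 34 -> codon position 3
WOBBLE_34 = {"G": ("C", "U"), "U": ("A", "G"), "C": ("G",), "A": ("U",)}


def _base_codons(anticodon: str) -> tuple[str, str]:
    """(codon positions 1-2, Watson-Crick codon position 3) read by an
    anticodon written 5'->3'."""
    a34, a35, a36 = anticodon
    return _COMP[a36] + _COMP[a35], _COMP[a34]


def decodable_codons(trnas, rules: WobbleRuleSet | None = None) -> set[str]:
    """Sense codons readable by a tRNA set under ``rules``.

    ``trnas`` is a list of anticodons (3-letter, 5'->3', RNA or DNA
    alphabet) or of (name, anticodon) pairs; names are only needed for the
    lysidine special case (trnI-CAU).  Stop codons are never returned.
    """
    rules = rules or WobbleRuleSet()
    entries: list[tuple[str, str]] = []
    for t in trnas:
        name, anticodon = t if isinstance(t, tuple) else ("", t)
        anticodon = _rna(anticodon)
        if len(anticodon) != 3 or set(anticodon) - set(_RNA):
            raise ValueError(f"invalid anticodon {anticodon!r}")
        entries.append((name, anticodon))

    decoded: set[str] = set()
    served_boxes: set[str] = set()  # family boxes touched by any tRNA
    u34_boxes: set[str] = set()  # family boxes with a U34 isoacceptor
    for name, anticodon in entries:
        prefix, wc3 = _base_codons(anticodon)
        a34 = anticodon[0]
        in_family = prefix in FAMILY_BOX_PREFIXES
        if in_family:
            served_boxes.add(prefix)
            if a34 == "U":
                u34_boxes.add(prefix)
        if a34 == "U" and in_family and rules.at_least("superwobble"):
            decoded.update(prefix + b for b in _RNA)
        else:
            decoded.update(prefix + b for b in WOBBLE_34[a34])
        if rules.lysidine_cau and name == "trnI-CAU" and anticodon == "CAU":
            decoded.add("AUA")
    if rules.at_least("two_out_of_three"):
        for prefix in served_boxes - u34_boxes:
            decoded.update(prefix + b for b in _RNA)
    return decoded & set(SENSE_CODONS)
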