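"""Genome I/O and the circular coordinate system.

Every module in this package works on circular DNA molecules with 1-based
inclusive coordinates.  A feature (or segment, or repeat copy) on a circular
sequence may wrap the origin, in which case it is stored with ``start > end``
rather than split in two; all interval arithmetic is modular.

Two length conventions coexist for an arc ``start..end`` on a circle of
length N:

``inclusive``
    the number of bases on the arc, ``((end - start) mod N) + 1``;
``printed``
    ``(end - start) mod N`` — one less than the base count.  Published
    segment tables for organellar master circles frequently use this
    convention, so it is exposed explicitly instead of being silently
    corrected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CircularSequence",
    "GenomeFeature",
    "AnnotatedGenome",
    "load_genome",
    "write_fasta",
    "write_genbank",
    "arc_interval",
    "gc_content",
    "revcomp",
    "features_to_bed",
    "features_to_gff3",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: feature kinds understood by downstream reports
FEATURE_KINDS = ("gene", "exon", "tRNA", "rRNA", "repeat")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CircularSequence:
    """A (possibly circular) DNA molecule.

    Parameters
    ----------
    id : sequence identifier.
    sequence : uppercase DNA over the alphabet {A, C, G, T, N}.
    is_circular : whether modular coordinate arithmetic applies.
    """

    id: str
    sequence: str
    is_circular: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-ACGTN characters: {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Bases on the arc ``start..end`` (1-based inclusive, may wrap)."""
        n = self.length
        if not (1 <= start <= n and 1 <= end <= n):
            raise ValueError(
                f"positions ({start}, {end}) out of range for length {n}"
            )
        if start <= end:
            return self.sequence[start - 1 : end]
        if not self.is_circular:
            raise ValueError(
                f"wrapping interval ({start}, {end}) on a linear sequence"
            )
        return self.sequence[start - 1 :] + self.sequence[:end]

    def rotate(self, offset: int) -> "CircularSequence":
        """Rotate so that old position ``offset+1`` becomes position 1."""
        n = self.length
        k = offset % n
        return CircularSequence(self.id, self.sequence[k:] + self.sequence[:k],
                                self.is_circular)


@dataclass(frozen=True)
class GenomeFeature:
    """An annotated interval: gene, exon, tRNA, rRNA or repeat copy.

    ``start``/``end`` are 1-based inclusive; ``start > end`` encodes a
    feature wrapping the origin of a circular sequence.  ``exon_index`` is
    the 1-based ordinal of an exon within its gene, in gene order.
    """

    name: str
    kind: str
    start: int
    end: int
    strand: str = "+"
    exon_index: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def length_on(self, n: int) -> int:
        return arc_interval(self.start, self.end, n, "inclusive")

    def contains(self, pos: int, n: int) -> bool:
        """Whether 1-based ``pos`` lies on this feature's arc (modular)."""
        if self.start <= self.end:
            return self.start <= pos <= self.end
        return pos >= self.start or pos <= self.end


@dataclass
class AnnotatedGenome:
    seq: CircularSequence
    features: list[GenomeFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.seq.length
        for f in self.features:
            if not (1 <= f.start <= n and 1 <= f.end <= n):
                raise ValueError(
                    f"feature {f.name!r} coordinates ({f.start}, {f.end}) "
                    f"outside [1, {n}]"
                )
            if f.start > f.end and not self.seq.is_circular:
                raise ValueError(
                    f"feature {f.name!r} wraps origin of linear sequence"
                )

    def feature_sequence(self, feat: GenomeFeature) -> str:
        s = self.seq.fetch(feat.start, feat.end)
        return revcomp(s) if feat.strand == "-" else s

    def by_kind(self, kind: str) -> list[GenomeFeature]:
        return [f for f in self.features if f.kind == kind]


def arc_interval(start: int, end: int, n: int, convention: str = "inclusive") -> int:
    """Length of the circular arc from ``start`` to ``end``.

    ``inclusive`` counts bases (``((end-start) mod N) + 1``); ``printed``
    returns ``(end-start) mod N``.  Wraps the origin when ``end < start``.
    """
    if not (1 <= start <= n and 1 <= end <= n):
        raise ValueError(f"positions ({start}, {end}) out of range [1, {n}]")
    diff = (end - start) % n
    if convention == "inclusive":
        return diff + 1
    if convention == "printed":
        return diff
    raise ValueError(f"unknown convention {convention!r}")


def gc_content(seq: str) -> float | None:
    """G+C fraction over unambiguous bases; ``None`` if no A/C/G/T present."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        return None
    return gc / (gc + at)


# ---------------------------------------------------------------------------
# readers / writers

def _kind_of(biotype: str) -> str | None:
    return {
        "gene": "gene",
        "CDS": "exon",
        "exon": "exon",
        "tRNA": "tRNA",
        "rRNA": "rRNA",
        "repeat_region": "repeat",
    }.get(biotype)


def _feature_name(sf: SeqFeature) -> str:
    for key in ("gene", "locus_tag", "product", "label"):
        if key in sf.qualifiers:
            return str(sf.qualifiers[key][0])
    return sf.type


def _genbank_features(record: SeqRecord, n: int) -> list[GenomeFeature]:
    out: list[GenomeFeature] = []
    for sf in record.features:
        kind = _kind_of(sf.type)
        if kind is None:
            continue
        name = _feature_name(sf)
        strand = "-" if sf.location.strand == -1 else "+"
        parts = list(sf.location.parts)
        # a two-part join touching the origin is read back as one wrapped
        # feature (start > end), whichever order the parts come in
        wrap = None
        if len(parts) == 2:
            p0, p1 = parts
            if int(p0.end) == n and int(p1.start) == 0:
                wrap = (int(p0.start) + 1, int(p1.end))
            elif int(p1.end) == n and int(p0.start) == 0:
                wrap = (int(p1.start) + 1, int(p0.end))
        if wrap is not None:
            out.append(GenomeFeature(name, kind, wrap[0], wrap[1], strand))
        elif len(parts) == 1 or kind not in ("exon", "gene"):
            loc = sf.location
            start, end = int(loc.start) + 1, int(loc.end)
            out.append(GenomeFeature(name, kind, start, end, strand))
        else:
            for i, part in enumerate(parts, start=1):
                out.append(
                    GenomeFeature(name, kind, int(part.start) + 1, int(part.end),
                                  strand, exon_index=i)
                )
    return out


def load_genome(path: str | Path, format: str | None = None,
                circular: bool | None = None) -> AnnotatedGenome:
    """Read the first record of a FASTA or GenBank file.

    Circularity is taken from the GenBank LOCUS topology when present;
    ``circular`` overrides it (and is the only source for FASTA input,
    defaulting to True — the package's subject matter is circular genomes).
    """
    path = Path(path)
    if format is None:
        format = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".genbank") \
            else "fasta"
    if format not in ("fasta", "genbank"):
        raise ValueError(f"unknown format {format!r}")
    try:
        records = list(SeqIO.parse(str(path), format))
    except Exception as exc:  # Biopython raises assorted ValueError subclasses
        raise ValueError(f"cannot parse {path} as {format}: {exc}") from exc
    if not records:
        raise ValueError(f"no records found in {path}")
    rec = records[0]
    seq = str(rec.seq).upper()
    if not seq:
        raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
    if circular is None:
        topology = rec.annotations.get("topology", "")
        circular = (topology == "circular") if format == "genbank" else True
    cs = CircularSequence(rec.id, seq, is_circular=circular)
    feats = _genbank_features(rec, cs.length) if format == "genbank" else []
    return AnnotatedGenome(cs, feats)


def _to_seqrecord(genome: AnnotatedGenome) -> SeqRecord:
    rec = SeqRecord(Seq(genome.seq.sequence), id=genome.seq.id, description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if genome.seq.is_circular else "linear"
    n = genome.seq.length
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        if f.start <= f.end:
            loc = FeatureLocation(f.start - 1, f.end, strand)
        else:  # wrap the origin as a two-part join
            loc = FeatureLocation(f.start - 1, n, strand) + FeatureLocation(0, f.end, strand)
        biotype = {"gene": "gene", "exon": "CDS", "tRNA": "tRNA",
                   "rRNA": "rRNA", "repeat": "repeat_region"}[f.kind]
        rec.features.append(SeqFeature(loc, type=biotype,
                                       qualifiers={"gene": [f.name]}))
    return rec


def write_fasta(genome: AnnotatedGenome | CircularSequence, path: str | Path) -> None:
    seq = genome.seq if isinstance(genome, AnnotatedGenome) else genome
    rec = SeqRecord(Seq(seq.sequence), id=seq.id, description="")
    SeqIO.write([rec], str(path), "fasta")


def write_genbank(genome: AnnotatedGenome, path: str | Path) -> None:
    SeqIO.write([_to_seqrecord(genome)], str(path), "genbank")


def features_to_bed(features: Iterable[GenomeFeature], n: int) -> str:
    """BED (0-based half-open) text; wrapping features are split in two."""
    lines = []
    for f in features:
        if f.start <= f.end:
            spans = [(f.start - 1, f.end)]
        else:
            spans = [(f.start - 1, n), (0, f.end)]
        for s0, e0 in spans:
            lines.append(f"chr\t{s0}\t{e0}\t{f.name}\t0\t{f.strand}")
    return "\n".join(lines) + "\n"


def features_to_gff3(features: Iterable[GenomeFeature], seqid: str, n: int) -> str:
    """GFF3 (1-based inclusive) text; wrapping features are split in two."""
    lines = ["##gff-version 3"]
    type_map = {"gene": "gene", "exon": "exon", "tRNA": "tRNA",
                "rRNA": "rRNA", "repeat": "repeat_region"}
    for f in features:
        spans = [(f.start, f.end)] if f.start <= f.end else [(f.start, n), (1, f.end)]
        for s, e in spans:
            lines.append(
                f"{seqid}\t organelle_dynamics\t{type_map[f.kind]}\t{s}\t{e}"
                f"\t.\t{f.strand}\t.\tID={f.name}".replace("\t ", "\t")
            )
    return "\n".join(lines) + "\n"


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_tsv(rows: Sequence[dict], path: str | Path, columns: Sequence[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")
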