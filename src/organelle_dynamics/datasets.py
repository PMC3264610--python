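"""Published reference inputs for *Boea hygrometrica* organellar genomes.

These are small printed datasets from the source study of the *B.
hygrometrica* chloroplast (cp, 153,493 bp) and mitochondrial (mt,
510,519 bp) genomes: the recombinationally active repeat pairs of the mt
master circle, the comparative GC table of chloroplast-derived insertions
(mtpt) across plant mt genomes, the cp tRNA isoacceptor set, and the
exon strand patterns of the three conserved trans-spliced genes.  They are
inputs to the analyses in this package, not outputs of it.
"""

from __future__ import annotations

import pandas as pd

from .repeats import RepeatPair

#: mt master-circle length (bp)
BOEA_MT_LENGTH = 510_519
#: cp genome length (bp)
BOEA_CP_LENGTH = 153_493

#: The three repeat pairs of the Boea mt genome with sequencing support for
#: recombination: two palindromic (P) pairs of 1,474 and 843 bp and one
#: forward (F) pair of 222 bp, with the published copy start coordinates.
BOEA_RECOMBINANT_REPEATS = (
    RepeatPair(length=1474, start1=51709, start2=232397, orientation="P"),
    RepeatPair(length=843, start1=42273, start2=108092, orientation="P"),
    RepeatPair(length=222, start1=153742, start2=405380, orientation="F"),
)

#: Published quadripartite region lengths of the Boea cp genome (bp).
BOEA_QUADRIPARTITE = {"ir": 25_450, "lsc": 84_692, "ssc": 17_901}

#: Published mt-segment table of the Boea master circle (segment label ->
#: (start, end, printed length)).  Printed length is (end - start) mod N.
BOEA_SEGMENT_TABLE = {
    "A": (43116, 51708, 8592),
    "B": (53183, 108091, 54908),
    "C": (108935, 153741, 44806),
    "D": (153964, 232396, 78432),
    "E": (233871, 405379, 171508),
    "F": (405602, 42272, 147189),
}

#: Exon strand patterns of the trans-spliced genes on the Boea master
#: circle, and the published master-circle segment holding each exon
#: (None where the segment table does not place the exon).
BOEA_TRANS_SPLICED_GENES = {
    "nad1": {"pattern": "---++", "segments": ["F", "D", "D", "A", None]},
    "nad2": {"pattern": "-----", "segments": ["D", "D", "B", "B", "B"]},
    "nad5": {"pattern": "+++++", "segments": ["B", "D", "D", "E", "E"]},
}

#: Comparative table of cp-derived sequences (mtpt) in plant mt genomes:
#: GC percentages of the cp and mt genomes, mtpt counts/lengths, and the
#: length-weighted GC of old (homolog found in another plant's mt genome)
#: vs new (no homolog) insertions.  NaN marks species with no new
#: insertions.  The first two species are non-seed plants (an alga and a
#: liverwort); the remaining nine are seed plants.
COMPARATIVE_MTPT_GC = pd.DataFrame(
    {
        "species": ["Chara", "Marchantia", "Cycas", "Triticum", "Oryza",
                    "Sorghum", "Zea", "Arabidopsis", "Nicotiana", "Vitis",
                    "Boea"],
        "seed_plant": [False, False, True, True, True, True, True, True,
                       True, True, True],
        "cp_gc": [26.19, 28.81, 39.45, 38.31, 38.99, 38.49, 38.46, 36.29,
                  37.85, 37.40, 37.59],
        "mt_gc": [40.90, 42.41, 46.92, 43.93, 43.85, 43.73, 43.93, 44.77,
                  44.96, 44.14, 43.27],
        "mtpt_n": [11, 16, 40, 57, 71, 49, 41, 30, 43, 51, 80],
        "mtpt_bp": [915, 1379, 17608, 15089, 34969, 33006, 24859, 5150,
                    11415, 68925, 53440],
        "old_n": [11, 16, 21, 54, 63, 44, 38, 30, 39, 33, 45],
        "new_n": [0, 0, 19, 3, 8, 5, 3, 0, 4, 18, 35],
        "old_gc": [54.54, 52.79, 45.85, 44.63, 40.62, 41.23, 44.55, 46.06,
                   46.20, 40.52, 41.59],
        "new_gc": [float("nan"), float("nan"), 40.75, 34.49, 37.72, 39.47,
                   42.62, float("nan"), 34.09, 34.08, 35.32],
    }
).set_index("species")

#: The published cp tRNA isoacceptor set of Boea: (gene name, anticodon).
#: Duplicated IR copies collapse to one entry per isoacceptor; 27 distinct
#: isoacceptors over 26 distinct anticodons (trnI-CAU and trnM-CAU share
#: the anticodon CAU but differ in identity and decoding).
BOEA_CP_TRNAS = (
    ("trnA-UGC", "UGC"), ("trnC-GCA", "GCA"), ("trnD-GUC", "GUC"),
    ("trnE-UUC", "UUC"), ("trnF-GAA", "GAA"), ("trnG-UCC", "UCC"),
    ("trnH-GUG", "GUG"), ("trnI-CAU", "CAU"), ("trnI-GAU", "GAU"),
    ("trnK-UUU", "UUU"), ("trnL-CAA", "CAA"), ("trnL-GAG", "GAG"),
    ("trnL-UAA", "UAA"), ("trnL-UAG", "UAG"), ("trnM-CAU", "CAU"),
    ("trnN-GUU", "GUU"), ("trnP-UGG", "UGG"), ("trnQ-UUG", "UUG"),
    ("trnR-ACG", "ACG"), ("trnR-UCU", "UCU"), ("trnS-GCU", "GCU"),
    ("trnS-UGA", "UGA"), ("trnT-GGU", "GGU"), ("trnV-GAC", "GAC"),
    ("trnV-UAC", "UAC"), ("trnW-CCA", "CCA"), ("trnY-GUA", "GUA"),
)

#: Published stop-codon usage of the Boea cp gene set (percent).
BOEA_CP_STOP_FRACTIONS = {"UAA": 40, "UAG": 33, "UGA": 27}
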