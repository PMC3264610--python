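# Methods

`organelle_dynamics` analyses the structural dynamics of circular
organellar genomes: maximal repeats and the recombination algebra they
induce on mitochondrial master circles, the quadripartite architecture of
chloroplast genomes, chloroplast-to-mitochondrion DNA transfer, and
anticodon-based codon decodability.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
benchmarks do and do not show.

## Coordinate model

All sequences are circular DNA with 1-based inclusive coordinates and
modular interval arithmetic; a feature may wrap the origin, stored as
`start > end` rather than split in two.  Two arc-length conventions are
exposed because published master-circle segment tables use
`end − start` (one less than the base count): `inclusive` =
`((end − start) mod N) + 1`, `printed` = `(end − start) mod N`.  The
`printed` convention is used only when reproducing such tables; every
internal conservation check uses `inclusive` (segment base counts plus
twice each repeat length must tile the circle exactly).

## Maximal repeat pairs

A repeat pair is two disjoint arcs whose sequences are equal (forward, F)
or reverse complements (palindromic, P), extendable in neither direction.
The finder indexes every k-mer of the circular sequence
(k = min(min_length, 16)) and extends co-occurring k-mers to maximal runs
along their diagonal; palindromic search runs the same machinery against
the reverse complement.  Runs covering the whole circle (rotation
periodicity) and pairs whose copies overlap are discarded.  Correctness is
defined by an exhaustive quadratic oracle (shift-comparison over every
circular diagonal) in the test suite, not by the implementation: the two
agree on 50+ random and planted genomes up to 20 kb.

The attached significance is the closed-form expectation
`E = orientations × N² × (1/4)^L` for chance maximal pairs of length ≥ L
in an i.i.d. uniform sequence.  Published repeat tables produced by
repeat-detection web services print E-values from an unspecified
statistic that this formula does not reproduce; the package therefore
reports its own documented expectation and never filters on it —
filtering is by `min_length` (default 50 bp, the conventional screen),
so downstream results are insensitive to the formula.

## Recombination algebra

A master circle (MC) with a set of disjoint two-copy repeats decomposes
into inter-repeat segments, labelled A, B, … from the lowest-coordinate
segment start.  A molecule is a cyclic list of signed units (segments and
repeat copies); the MC carries all units on `+` except the second copy of
each palindromic pair.  Recombination at a pair whose copies have opposite
signs (*inverted*) reverses and strand-flips the arc strictly between the
copies, producing one isomeric circle; at a pair with equal signs
(*direct*) it excises two subgenomic circles, each keeping one repeat
copy.  Repeat copies persist at the junctions — biologically the repeat is
retained, and it keeps every state well formed.

Molecules are compared after canonicalization: the lexicographic minimum
over all rotations of the unit-token string and of the strand-flipped,
order-reversed string.  The two possible arcs of an inversion then yield
the same canonical product (asserted in tests, not assumed).  Isomer
enumeration is a breadth-first closure applying inversions at every
currently inverted pair of every reached circle until no new canonical
state appears; excision products are recorded but not expanded, and the
isomer count excludes the MC.  Multi-event states are deliberately
allowed: with the published three-pair configuration the closure
terminates at exactly four isomers, and an unpruned enumeration of all
event sequences up to depth six reaches the same set on random
configurations with ≤ 4 pairs.

Per-molecule gene reports compose each exon's annotated strand with the
sign its host segment carries in the molecule, yielding +/− exon-order
patterns; genes with exons on both strands are flagged cross-strand
(trans-splicing candidates), and exons hosted by units absent from an
excision product are flagged missing.

## Quadripartite detection

The longest palindromic maximal pair at least `min_ir` long (default
1000 bp) defines IRa/IRb; the longer inter-IR arc is the LSC, the shorter
the SSC.  IRs are required to be exact reverse complements — the detector
is a thin layer over the repeat finder, which keeps the oracle simple; a
mismatch-tolerant IR extension is out of scope.  Equal-length competing
candidate pairs raise an error demanding a manual choice.  Every returned
map satisfies `2·IR + LSC + SSC = N`, and the per-copy IR fraction is
reported (that convention reproduces the published per-copy percentages).

## Plastid-derived insertions (mtpt)

Detection is local alignment of the mt genome against the same species'
cp genome under the conventional screen: identity ≥ 80 %, E ≤ 1e−5,
length ≥ 50 bp; homolog searches additionally require coverage ≥ 50 % of
the query.  The built-in aligner is seed-and-extend:

* exact 9-mer seeds on both target strands, grouped by diagonal and
  clustered (gap ≤ 60 bp).  Nine was chosen so that a fragment at the
  recall-guarantee boundary of the detector — 100 bp at 85 % identity,
  i.e. `min_identity + 0.05` and `2 × min_length` — contains an exact
  seed with probability > 0.999 (a 20 000-trial placement simulation;
  11-mers reach only ≈ 0.995);
* ungapped x-drop extension (match +1, mismatch −3, x-drop 40) followed
  by restriction to the maximal-scoring subsegment, so terminal
  mismatches are trimmed;
* chaining of co-linear extensions on nearby diagonals (drift ≤ 20,
  query gap or overlap ≤ 60 bp), re-scored by edit distance so small
  indels are represented honestly; micro-alignments scoring < 20 are
  excluded from chaining (the thresholds discard them regardless);
* greedy resolution of mt-side overlaps to the highest-scoring
  non-overlapping set (score, then length, then leftmost) — published
  fragment counts depend on this merge rule, which is why count-level
  comparisons against deposited genomes carry a ±5 % tolerance;
* Karlin–Altschul significance `E = K·m·n·e^(−λS)` with λ solved for the
  scoring scheme (λ ≈ 1.374 for +1/−3) and K = 0.3, a logged constant.

An insertion is *old* if its mt-side sequence aligns to at least one
other-species mt genome at the thresholds (coverage ≥ 50 %), else *new*;
region of origin (LSC/SSC/IR) is the quadripartite region containing the
midpoint of the cp-side interval.  Summaries report counts, total bp,
fraction of the mt genome, and length-weighted GC percent per age class.
GC excludes ambiguous bases from numerator and denominator.

Correlation of GC values across species uses the sample Pearson r; the
comparative table in `datasets` reproduces the published coefficients as
r (0.69 for cp-GC vs new-insertion GC over the eight species with new
insertions; 0.63–0.64 for mt-GC vs old-insertion GC over the nine seed
plants), although the source labels them r² — the r interpretation is the
one that reproduces the printed numbers, and including the two non-seed
plants in the old-GC correlation flips its sign, so the seed-plant subset
is the documented choice.  The old-vs-new GC contrast uses Welch's
two-sample t with Satterthwaite degrees of freedom.

tRNA transfer classification aligns each mt tRNA against all same-species
cp tRNAs (both strands) by edit distance; identity
`1 − dist/max(len)` ≥ 80 % marks it cp-derived.  For ~75-nt tRNAs at that
identity the match expectation is far below the E-value cutoff, so the
identity and coverage gates dominate.

## Codon decodability

Codon usage counts frame-0 codons over a CDS set (tables print RNA
codons); stop fractions are computed over terminal codons only, and
internal stops raise warnings (a signature of RNA editing, whose
inference is out of scope).  Decodability applies a configurable wobble
policy to anticodon position 34: strict (G34→{C,U}, U34→{A,G}, C34→{G},
A34→{U}); superwobble (U34 additionally reads all four codons of an
unsplit family box); two-out-of-three (a family box with no U34
isoacceptor is unlocked by any tRNA serving it).  The lysidine-type
modification of trnI-CAU (reads AUA besides AUG) is on by default.  The
published claim that the cp tRNA set decodes all 61 sense codons does not
state its wobble convention; the rule set above is this package's
declared model, under which the published 27-isoacceptor set decodes
exactly 61 (48 under strict, 56 under superwobble alone — the
two-out-of-three step is needed precisely because the set has no
trnT-UGU).  Policy outputs are provably monotone and tested as such.

## Synthetic data

Generators produce i.i.d. backgrounds at a requested GC (defaults: 0.43
mt-like, 0.38 cp-like, mirroring the study system's genome-wide values)
with planted structure returned as machine-checkable truth tables:
repeat pairs (copied verbatim or reverse-complemented, with flanking
bases forced to mismatch so planted lengths are exactly maximal),
quadripartite layouts (LSC + IRa + SSC + revcomp(IRa), junction-adjacent
bases forced non-pairing for the same reason), cp-derived insertions
mutated to an exact identity (substitution-only by default: exactly
`round((1−identity)·L)` substitutions at distinct uniform positions,
never back to the original base, so recall/precision checks are
deterministic; an indel mode exists for robustness tests), and mixed
native/cp-copied tRNA sets.  All randomness flows through NumPy's
PCG64 `default_rng`, so a seed pins outputs across platforms.

Default problem sizes are scaled down from the study system — mt-like
60 kb (vs 510 kb) and cp-like 15 kb (vs 153 kb) — which keeps the
exhaustive oracles and 20-scenario sweeps comfortably fast while leaving
seed statistics (k-mer collision rates per diagonal) in the same regime.
What passing these benchmarks shows is exact-arithmetic correctness and
detector sensitivity under the substitution-only model; what they do not
show is robustness to assembly artefacts, heavy indel divergence,
near-identical (non-exact) IRs, or nested/overlapping repeat families,
none of which the simulator emulates.

## Known limitations

* Exact repeats only; degenerate (mismatch-tolerant) repeats and
  transposable-element classification are out of scope.
* Which repeat pairs are recombinationally active cannot be decided from
  sequence alone (the study used mate-pair sequencing evidence), so pair
  selection is a user input; isomer stoichiometry is not modelled.
* The built-in aligner's fragment counts can differ from other local
  aligners at the merge-rule level; swapping in an external
  BLAST-compatible backend changes counts within the documented ±5 %.
* GenBank records whose genes wrap the origin must use either a two-part
  join touching position 1/N (collapsed on read) or a wrapped
  `start > end` encoding; other exotic location forms are not handled.
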