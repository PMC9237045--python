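# Methods

This note records the models, conventions and numerical choices behind
`retrojoin`, in the spirit of a methods supplement: what the code computes,
what the synthetic data does and does not emulate, and where the design was
genuinely open.

## Coordinate and scoring conventions

All coordinates are 0-based, half-open. The CRISPR cut site and L1
endonuclease nick positions are *between-base* offsets; the cut site lies
3 bp 5' of the PAM on the protospacer strand.

One pairwise scoring contract is used everywhere: match +1, mismatch −2,
and a gap of length L costs 2 + L (affine; open 2 charged once, extend 1
per base). These conservative nucleotide-alignment settings make every
threshold in the pipeline (minimum reportable score 30, ambiguity
score-difference 4, minimum junction alignment lengths) directly
interpretable in match units. The implementation delegates the dynamic
program to `Bio.Align.PairwiseAligner`; the test suite checks it against an
independently written Gotoh DP on hundreds of random pairs. Among
co-optimal alignments the one with the leftmost query start, then leftmost
reference start, is taken (enumeration capped at 64 co-optima); in
practice the aligner resolves net-zero end extensions toward the shorter
alignment, and the simulator's truth models reproduce exactly that
behavior (see below).

Genome-scale placement is seed-and-extend: an exact k-mer index (k = 13,
sampled every ⌊k/2⌋ bases on both strands) proposes windows clustered by
alignment diagonal; each window is then aligned with the full affine DP, so
reported scores follow the contract exactly. Queries longer than 600 nt —
event-scale fragments rather than reads — are resolved by maximal exact
seed extension per diagonal instead of the quadratic DP; at those lengths
and gap costs the DP would select the same placement (crossing a splice or
junction boundary never pays), and the shortcut keeps multi-kilobase
fragment mapping effectively instantaneous.

## Junction model

For each insertion-bearing mate, two alignments are computed on the read:
one to the target locus, one to the attributed insert source. With the
target alignment ending at read position `t_end` and the insert alignment
starting at `i_start`, the junction has microhomology `t_end − i_start`
when the intervals overlap, and an "other sources" linker gap of
`i_start − t_end` otherwise — a coordinate-overlap definition, not a
sequence re-inspection, so when sequencing error corrupts an overlap base
the alignment-derived value stands. Forward mates interrogate the left DSB
end; reverse mates are reverse-complemented into locus orientation and
interrogate the right end (their target alignment must then end within
8 bp of the 3' end of the processed sequence). Validity filters: target
alignment within 8 bp of the proximal read end and ≥ 18 bp long; insert
alignment ≥ 30 bp (≥ 10 bp for pegRNA-scaffold junctions, which must also
contain the programmed edited base and align in minus orientation).
Junction offsets are signed base pairs relative to the cut site (negative
= 5' on the reference plus strand). Reads whose insert alignment is wholly
contained in the target alignment are rejected as non-informative.

Because the definition is alignment-based, the recovered microhomology can
exceed the generator's planted value whenever flanking sequence happens to
extend the optimal alignment past the biological junction (a mismatch
followed by enough chance matches pays for itself at −2/+1). On fully
random constructs this affects a few percent of junctions; it is a
property of the definition, not an implementation error. The constructed
oracle suite therefore draws the target flank over {A,C} and the insert
body over {G,T} with the insert reference beginning/ending exactly at the
junction: no alignment, gapped or not, can cross the planted boundary, so
recovery must be exact there — and is, over the full
(microhomology 0–10) × (gap 0–10) × side × orientation grid.

## Source attribution

Each trimmed insert is aligned to every reference through one shared index.
Attribution rules, in order: (1) an insert whose reporter alignment lies in
a sequence element recorded as shared with the lentiviral plasmid — and
which the plasmid explains at least as well — is credited to the plasmid;
(2) likewise for elements shared with endogenous L1Hs; (3) otherwise the
best-scoring reference wins, with pegRNA-scaffold hits on the editor
plasmid labelled PEGRNA; (4) genomic attributions additionally require the
best placement to beat the runner-up by ≥ 4 score units (the mapq ≥ 2
analogue); anything under score 30 is unclassified. The shared elements are
explicit intervals carried by the reference set rather than rediscovered at
run time — declarative, testable, and the same exclusion logic either way.
Within a source, records whose reference start *and* end are each < 4 bp
from an already-kept record are merged (greedy over (start, end) order;
idempotent). Fragment maps bin by 100 bp and report both per-bin fragment
overlap counts and fragment-center counts, stratified by orientation.

## PolyA-seq calling

Masked reads (barcode+primer → N) are aligned genome-wide; the junction is
the genomic coordinate of the 5'-most aligned read base (low edge for
plus-strand placements, high edge for minus). Filter flags are computed
independently — low_score (< 30), ambiguous (runner-up within < 4; a
difference of exactly 4 is kept), gapped (any gap ≥ 10 nt, reading the
"10-nucleotide gaps" artifact rule as a split-alignment guard), pcr_repeat
(same junction position and in-read alignment start < 3 bp from a kept
read; greedy over sorted starts), and ligation_artifact — so the surviving
set is invariant to filter order. The ligation-artifact predicate is
pluggable; the default flags junctions whose centred 4-mer is a blunt
HaeIII boundary (GG|CC), the enzyme used for fragmentation, and passes
(with a warning) within 2 bp of a contig end.

The poly(A) tract is the read-span of the best local alignment against a
200-bp poly(A) reference, reported only when it starts in the read before
the genomic alignment does (ensuring tail-then-flank order) and when
≥ 11 nt — the word-size floor of the underlying aligner convention.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions the analyses are specified under.

**Reference universe.** Two i.i.d.-uniform ACGT chromosomes (120 kb +
100 kb) with: one CRISPR target locus (protospacer + NGG PAM; cut 3 bp 5'
of the PAM); 600 planted endonuclease consensus sites (5'-TTAAAAA-3' on a
random strand, nick between TT and AAAAA), spaced away from the locus, the
duplicated segment and each other — planted sites are meant to be
unambiguous truth anchors, so contexts where a nearby homopolymer run
could let a poly(A)-primed alignment jump the nick are rejected at
planting; one 1-kb segment duplicated across chromosomes for
mapping-ambiguity tests. The 7-kb reporter cassette carries ORF1, ORF2, a
3' UTR with an antisense GFP interrupted by a 900-bp intron, and an SV40
poly(A); its geometry mirrors the published construct, so the intron-assay
primer pair spans 1192 bp unspliced and 292 bp spliced. Vector backbone
(reporter ↔ lenti plasmid) and L1Hs-homologous (reporter ↔ L1Hs) elements
of 150 bp each sit at the reporter 5' end, outside the ORFs, and are
recorded as shared intervals; the pegRNA scaffold is embedded in the
editor plasmid.

**Amplicon events.** Each event resects both break ends by 0–8 bp and
inserts a fragment: reporter (3'-anchored with a uniform 5'-truncation
point, spliced with probability 0.5 — the truncation model is a
configuration knob, since the empirical truncation distribution is not
quantified), genomic (uniform within ±5 kb of the cut, excluding the
amplicon footprint; 150–400 bp), plasmid, pegRNA or L1Hs, in either
orientation. Microhomology (default: direct joints plus a 1–6 bp
decreasing profile) is planted by *searching* the source for a position
whose preceding bases reproduce the break-end sequence; if no site exists
for a large draw the largest achievable value is planted instead. The
truth table never trusts the plant: every junction's (mh, gap) is
re-measured on the finished construct by direct string extension, the same
coordinate-overlap definition the analysis uses, so ground truth is exact
by construction. "Other sources" linkers (random 5–30 bp fillers, 10 % of
events) are redrawn until they cannot extend either alignment. Amplicon reporter inserts carry no poly(A) tail — the tail is
the PolyA-seq dialect's concern — which keeps both junction truths exact.

**PolyA-seq reads.** barcode + nested primer + poly(A) (uniform 15–75 nt)
+ downstream genomic flank, EN-dependent events at planted nicks and
EN-independent events uniform within ±5 kb of the cut. Two truth fields
account for what is *measurable*: the recorded poly(A) length is the full
junction homopolymer run under the alignment scoring (drawn tail plus
templated genomic A's, including mismatch- or gap-bridged extensions the
aligner would make — computed by an independent small dynamic program, not
by the aligner itself), and `true_junction_call` is the junction position
after any such extension of the genomic alignment's 5' edge. On error-free
reads, recovery against these fields is exact (verified at n ≈ 4,000
across reference seeds).

**Edited reads.** A programmed substitution at a chosen locus position in
an exact fraction of reads, with per-position Phred control (site and
flank qualities) so NQS callability is itself part of the truth table.
Qualities elsewhere are Normal(36, 3) clamped to [2, 40], Phred+33;
substitution errors at a configurable per-base rate (default 10⁻³;
error-free for oracle-grade runs). Everything derives from a single seed;
identical configurations produce byte-identical FASTQ/FASTA/TSV.

**What the generator does not emulate.** Real base-composition and repeat
structure of a mammalian genome (beyond the planted duplication), indel
sequencing errors, PCR chimeras, library-chemistry biases (ligation,
biotin capture, emulsion PCR), and transcription-coupled features. Passing
tests therefore demonstrate correctness of the *computations* under
realistic read structure — not robustness to every artifact of real
libraries.

## Editing efficiency

Reads failing mean quality < 20 or length < 50 are excluded; alignments
must span > 80 bp. A mutation is trusted only if its base has Phred ≥ 30
and the five read bases on either side have Phred ≥ 20; positions near a
read end evaluate only the existing flanks (a strict mode requiring all
five is available). Efficiency is 100 × (NQS-passing expected edits) /
(pass-filter reads), computable over any read subset (e.g. only
insertion-bearing reads), and NA when no read passes. Whether the original
NQS notion extends to indels is undefined here; deletion edits would need
the two flanking bases NQS-clean, and only substitutions are exercised.

## Motif analytics

Flanks are the 11 bases covering positions −3..+8 around the insertion
point, with position 0 the first base 3' of the junction on the motif
strand; minus-strand insertions are reverse-complemented so a canonical
TPRT site always reads 5'-TT|AAAAA-3' across the nick (the strand
convention is configurable in the extraction call). PWMs use plug-in
column frequencies without pseudocounts — with 30 flanks per window,
zero-probability cells are expected and 0·log 0 ≡ 0 handles them; no
small-sample correction is applied, keeping the score the plain sum of
per-column information content (0–22 bits over 11 columns). Windows are
consecutive, non-overlapping groups of exactly 30 position-sorted
insertions per chromosome (trailing partial window dropped); the
chromosome curve is a natural cubic *interpolating* spline through
(window centre, motif score) — it passes through every point, degrades to
a straight segment for two windows, and raises an error below two.

## Problem sizes and tolerances

The test and acceptance runs use desk-scale sizes chosen to give tight
statistics while keeping the full suite under a minute of alignment time:
504 constructed junctions, 500 alignment-oracle pairs, 2,000 classified
inserts (plus a 600-insert reporter-free control), 200-event fragment-map
simulations, 3,000 EN-dependent + 2,000 mixed PolyA-seq reads, 800
poly(A)-recovery reads, 100-read efficiency cohorts. Exactness is asserted
where the truth model is exact (constructed junctions, error-free PolyA-seq
recovery, NQS efficiency); distributional checks use binomial 3σ bands;
classification accuracy is asserted at ≥ 95 % (measured ≈ 99.5 %, the gap
being the documented shared-element reattributions); pipeline-level
junction recovery on fully random simulations is asserted at ≥ 85 % exact
to leave room for the coordinate-overlap ambiguity discussed above.

## Known limitations

* Classification runs on the forward-mate insert; mate-pair fragment
  reconstruction between the two break ends is out of scope (ends are
  analyzed independently).
* Exact-duplicate collapse treats recurrent identical junctions as PCR
  repeats; for 3'-anchored reporter insertions this deflates counts, as in
  any amplicon assay with this dedup rule.
* The ligation-artifact predicate implements the HaeIII blunt-boundary
  example; other ligation chimera classes would need their own predicates
  (the hook is pluggable).
* The microhomology reported for a junction is the optimal-alignment
  overlap; where a suboptimal alignment would instead explain the joint as
  a short gap, the optimal-alignment value is always taken.
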