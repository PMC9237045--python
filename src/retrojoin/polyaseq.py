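"""Genome-wide de novo insertion junction calling from PolyA-seq reads.

A masked read (barcode+primer replaced by N) is aligned to the genome
through the seeded index; the junction is the genomic position of the 5'
end of the aligned read (strand-aware: for minus-strand alignments this is
the high-coordinate edge).  Artifact filters, each an independent flag:

* ``low_score``        — best alignment score < 30;
* ``ambiguous``        — runner-up placement within < 4 score units;
* ``gapped``           — best alignment contains a gap of >= 10 nt;
* ``pcr_repeat``       — same junction position and in-read alignment
                          start < 3 bp from an already-kept read;
* ``ligation_artifact``— junction at a blunt HaeIII boundary (GG|CC
                          4-mer centred on the junction; the predicate is
                          pluggable).

A junction is reported iff its flag set is empty.  The poly(A) tract is
measured as the read-span of the best alignment against a 200-bp poly(A)
reference, accepted only when it starts in the read before the genomic
alignment does, and only when >= 11 nt (the aligner word-size floor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .align import Alignment, AlignParams, DEFAULT_PARAMS, GenomeIndex, local_align

MIN_SCORE = 30
AMBIG_SCORE_DIFF = 4
MAX_ALLOWED_GAP = 10  # gaps of this length or longer flag the alignment
PCR_REPEAT_DELTA = 3
MIN_POLYA = 11
POLYA_REF = "A" * 200


@dataclass
class PolyAJunction:
    read_id: str
    chrom: str = ""
    pos: int = -1
    strand: str = "+"
    align_score: float = 0.0
    polya_len: int = 0  # 0 = undetected
    read_aln_start: int = -1
    filter_flags: set[str] = field(default_factory=set)

    @property
    def reported(self) -> bool:
        return not self.filter_flags and self.pos >= 0


def genome_align_masked(
    read_seq: str,
    index: GenomeIndex,
    params: AlignParams = DEFAULT_PARAMS,
) -> list[Alignment]:
    """Candidate placements of the masked read, best first.  The masked
    prefix and the poly(A) run stay unaligned by construction (N matches
    nothing in the genome; the A-run only matches where the genome is
    A-rich)."""
    return index.align(read_seq, params)


def filter_alignments(candidates: list[Alignment]) -> set[str]:
    """Score/ambiguity/gap flags for a candidate list (empty = no
    acceptable alignment at all, flagged low_score)."""
    flags: set[str] = set()
    if not candidates or candidates[0].score < MIN_SCORE:
        flags.add("low_score")
    if len(candidates) > 1 and (candidates[0].score - candidates[1].score) < AMBIG_SCORE_DIFF:
        flags.add("ambiguous")
    if candidates and candidates[0].max_gap_len >= MAX_ALLOWED_GAP:
        flags.add("gapped")
    return flags


def junction_position(aln: Alignment) -> int:
    """Genomic position of the 5'-most aligned read base, strand-aware:
    the low-coordinate alignment edge for plus-strand placements, the
    high-coordinate edge for minus-strand ones."""
    return aln.r_start if aln.orientation == "+" else aln.r_end


def default_ligation_predicate(genome: dict[str, str], chrom: str, pos: int) -> bool | None:
    """True iff the 4-mer centred on the junction is a blunt HaeIII
    boundary (GG|CC); None when the position is within 2 bp of a contig
    end (treated as pass, with the caller free to warn)."""
    seq = genome[chrom]
    if pos < 2 or pos + 2 > len(seq):
        return None
    return seq[pos - 2 : pos + 2] == "GGCC"


def flag_ligation_artifacts(
    junction: PolyAJunction,
    genome: dict[str, str],
    predicate: Callable[[dict[str, str], str, int], bool | None] = default_ligation_predicate,
) -> None:
    """Flag a junction in place when the ligation-artifact predicate
    fires."""
    hit = predicate(genome, junction.chrom, junction.pos)
    if hit:
        junction.filter_flags.add("ligation_artifact")


def dedup_pcr_repeats(junctions: list[PolyAJunction]) -> None:
    """Flag PCR repeats in place: among reads sharing an identical genomic
    junction position (and strand), any read whose in-read alignment start
    is < 3 bp from an already-kept read is collapsed (greedy over reads
    sorted by alignment start, then id)."""
    groups: dict[tuple[str, int, str], list[PolyAJunction]] = {}
    for j in junctions:
        if j.pos < 0:
            continue
        groups.setdefault((j.chrom, j.pos, j.strand), []).append(j)
    for group in groups.values():
        kept_starts: list[int] = []
        for j in sorted(group, key=lambda x: (x.read_aln_start, x.read_id)):
            if any(abs(j.read_aln_start - s) < PCR_REPEAT_DELTA for s in kept_starts):
                j.filter_flags.add("pcr_repeat")
            else:
                kept_starts.append(j.read_aln_start)


def measure_polya(
    read_seq: str,
    genomic_q_start: int,
    params: AlignParams = DEFAULT_PARAMS,
) -> int:
    """Poly(A) tract length from the read's alignment to a 200-bp poly(A)
    reference; 0 (undetected) when shorter than 11 nt or when the poly(A)
    alignment does not start before the genomic alignment in the read."""
    pa = local_align(read_seq, POLYA_REF, params)
    if pa is None:
        return 0
    length = pa.q_end - pa.q_start
    if length < MIN_POLYA:
        return 0
    if pa.q_start >= genomic_q_start:
        return 0
    return length


def call_junctions(
    reads: list[tuple[str, str]],
    index: GenomeIndex,
    genome: dict[str, str],
    params: AlignParams = DEFAULT_PARAMS,
    ligation_predicate: Callable = default_ligation_predicate,
    measure_tails: bool = True,
) -> list[PolyAJunction]:
    """Full junction calling over masked (read_id, seq) pairs.

    Every read yields one PolyAJunction carrying its filter flags; the
    reported set is ``[j for j in result if j.reported]``.  Filters are
    independent, so their application order does not change the surviving
    set.
    """
    out: list[PolyAJunction] = []
    for read_id, seq in reads:
        cands = genome_align_masked(seq, index, params)
        flags = filter_alignments(cands)
        j = PolyAJunction(read_id=read_id, filter_flags=flags)
        if cands:
            best = cands[0]
            j.chrom = best.ref_name
            j.pos = junction_position(best)
            j.strand = best.orientation
            j.align_score = best.score
            j.read_aln_start = best.q_start
            if measure_tails:
                j.polya_len = measure_polya(seq, best.q_start, params)
        out.append(j)
    with_pos = [j for j in out if j.pos >= 0]
    dedup_pcr_repeats(with_pos)
    for j in with_pos:
        flag_ligation_artifacts(j, genome, ligation_predicate)
    return out
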