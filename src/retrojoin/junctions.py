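"""Break-end junction analysis: microhomology, "other sources" gaps, and
junction position relative to the cut site.

For each insertion-bearing read the target-locus alignment and the insert
alignment are computed on the read; the overlap of their read intervals is
the junction microhomology, a gap between them is unmatched "other
sources" linker sequence.  Forward mates interrogate the left end of the
DSB, reverse mates the right end (the reverse mate is reverse-complemented
into locus orientation, so its target alignment sits at the 3' end of the
processed sequence).

Validity filters, all on the read: the target alignment must start within
8 bp of the proximal read end, span >= 18 bp, and the insert alignment
must span >= 30 bp (>= 10 bp for pegRNA scaffold junctions, which must
additionally contain the edited base and align in minus orientation).
"""

from __future__ import annotations

from dataclasses import dataclass

from .align import Alignment, AlignParams, DEFAULT_PARAMS, best_local_alignment, local_align, revcomp

MAX_START_OFFSET = 8
MIN_TARGET_ALN = 18
MIN_INSERT_ALN = 30
MIN_PEGRNA_ALN = 10


@dataclass
class JunctionRecord:
    read_id: str
    dsb_side: str  # "left" | "right"
    insert_source: str = ""
    orientation: str = "+"  # insert orientation on the locus plus strand
    mh_len: int = 0
    gap_len: int = 0
    junction_offset: int = 0  # signed bp relative to cut site (negative = 5')

    @property
    def gap_label(self) -> str:
        return "other_sources" if self.gap_len > 0 else "none"


@dataclass
class Rejection:
    read_id: str
    dsb_side: str
    reason: str


def _resolve(t_end: int, i_start: int) -> tuple[int, int]:
    if i_start <= t_end:
        return t_end - i_start, 0
    return 0, i_start - t_end


def junction_for_side(
    read_id: str,
    read_seq: str,
    target_ref: str,
    insert_ref: str | None,
    side: str,
    cut_site_ref: int,
    insert_source: str = "",
    params: AlignParams = DEFAULT_PARAMS,
    insert_aln: Alignment | None = None,
    insert_candidates: list[Alignment] | None = None,
    min_insert_aln: int = MIN_INSERT_ALN,
) -> JunctionRecord | Rejection:
    """Junction record for one mate, or a Rejection with a reason code.

    ``read_seq`` is the mate as sequenced; ``side`` is "left" for forward
    mates and "right" for reverse mates.  ``cut_site_ref`` is the cut-site
    coordinate on ``target_ref``.  A precomputed ``insert_aln`` (on the
    locus-oriented sequence) may be supplied, e.g. by the pegRNA variant;
    alternatively ``insert_candidates`` (score-sorted, locus-oriented) lets
    the call pick the best placement not contained in the target alignment
    — needed when insert and target share a reference (genomic inserts).
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be left or right, got {side!r}")
    seq = read_seq if side == "left" else revcomp(read_seq)
    n = len(seq)

    t_aln = local_align(seq, target_ref, params)
    if t_aln is None:
        return Rejection(read_id, side, "no_target_alignment")
    if t_aln.q_len < MIN_TARGET_ALN:
        return Rejection(read_id, side, "target_alignment_too_short")
    if side == "left" and t_aln.q_start > MAX_START_OFFSET:
        return Rejection(read_id, side, "target_start_too_far")
    if side == "right" and (n - t_aln.q_end) > MAX_START_OFFSET:
        return Rejection(read_id, side, "target_start_too_far")

    def contained(a: Alignment) -> bool:
        return t_aln.q_start <= a.q_start and a.q_end <= t_aln.q_end

    i_aln = insert_aln
    if i_aln is None and insert_candidates is not None:
        for cand in insert_candidates:
            if not contained(cand):
                i_aln = cand
                break
    if i_aln is None and insert_ref:
        i_aln = best_local_alignment(seq, insert_ref, params)
    if i_aln is None:
        return Rejection(read_id, side, "no_insert_alignment")
    if i_aln.q_len < min_insert_aln:
        return Rejection(read_id, side, "insert_alignment_too_short")
    if contained(i_aln):
        return Rejection(read_id, side, "insert_contained_in_target")

    if side == "left":
        mh, gap = _resolve(t_aln.q_end, i_aln.q_start)
        offset = t_aln.r_end - cut_site_ref
    else:
        # mirrored: the insert precedes the flank on the locus-oriented
        # sequence; overlap of the insert end with the flank start
        mh, gap = _resolve(n - t_aln.q_start, n - i_aln.q_end)
        offset = t_aln.r_start - cut_site_ref

    return JunctionRecord(
        read_id=read_id,
        dsb_side=side,
        insert_source=insert_source,
        orientation=i_aln.orientation,
        mh_len=mh,
        gap_len=gap,
        junction_offset=offset,
    )


def pegrna_junction(
    read_id: str,
    read_seq: str,
    target_ref: str,
    pegrna_ref: str,
    edited_base_pos: int,
    side: str,
    cut_site_ref: int,
    params: AlignParams = DEFAULT_PARAMS,
) -> JunctionRecord | Rejection:
    """Junction of a pegRNA-scaffold insertion at a prime-editing site.

    The scaffold alignment must contain the edited base (a position on the
    pegRNA reference), align in minus orientation, and span >= 10 bp.
    """
    seq = read_seq if side == "left" else revcomp(read_seq)
    i_aln = best_local_alignment(seq, pegrna_ref, params)
    if i_aln is None:
        return Rejection(read_id, side, "no_pegrna_alignment")
    if i_aln.orientation != "-":
        return Rejection(read_id, side, "pegrna_plus_orientation")
    if i_aln.q_len < MIN_PEGRNA_ALN:
        return Rejection(read_id, side, "pegrna_alignment_too_short")
    if not (i_aln.r_start <= edited_base_pos < i_aln.r_end):
        return Rejection(read_id, side, "pegrna_missing_edited_base")
    return junction_for_side(
        read_id,
        read_seq,
        target_ref,
        pegrna_ref,
        side,
        cut_site_ref,
        insert_source="PEGRNA",
        params=params,
        insert_aln=i_aln,
        min_insert_aln=MIN_PEGRNA_ALN,
    )


def mh_histogram(
    junctions: list[JunctionRecord],
) -> dict[tuple[str, str], dict[int, int]]:
    """Microhomology-length histograms stratified by (side, orientation);
    gap junctions are tallied under key -1 ("other sources").  Total mass
    equals the number of accepted junctions."""
    out: dict[tuple[str, str], dict[int, int]] = {}
    for j in junctions:
        key = (j.dsb_side, j.orientation)
        hist = out.setdefault(key, {})
        k = -1 if j.gap_len > 0 else j.mh_len
        hist[k] = hist.get(k, 0) + 1
    return out
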