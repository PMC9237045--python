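"""Quality-aware mutation calling and editing efficiency.

A read contributes to the efficiency denominator when it passes read QC
(mean Phred >= 20 and length >= 50) and alignment QC (aligned span > 80 bp
on the target reference).  A mutation is trusted only under the
Neighborhood Quality Standard: Phred >= 30 at the mutated base and >= 20
at the five read bases on either side (positions near the read end
evaluate only the existing flanks unless strict mode is on).  Editing
efficiency is the percentage of pass-filter reads carrying an NQS-passing
mutation matching the expected edit at the target position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import Alignment, AlignParams, DEFAULT_PARAMS, best_local_alignment
from .readprep import Read

MIN_MEAN_QUALITY = 20.0
MIN_READ_LEN = 50
MIN_ALIGNED_LEN = 80  # aligned length must exceed this
NQS_SITE_Q = 30
NQS_FLANK_Q = 20
NQS_FLANK_N = 5


@dataclass
class EditCall:
    read_id: str
    pass_read_filters: bool = False
    aligned_len: int = 0
    read_base: str = ""
    ref_base: str = ""
    phred: int = -1
    nqs_pass: bool = False
    edited_at_target: bool = False


def read_qc(read: Read) -> bool:
    if len(read.seq) < MIN_READ_LEN:
        return False
    return float(np.mean(read.qual)) >= MIN_MEAN_QUALITY


def alignment_qc(aln: Alignment | None) -> bool:
    return aln is not None and aln.q_len > MIN_ALIGNED_LEN


def _read_pos_of_ref(aln: Alignment, ref_pos: int) -> int | None:
    """Read coordinate aligned to a reference position (None if the
    position falls in a gap or outside the alignment).  Only valid for
    plus-orientation alignments."""
    if not (aln.r_start <= ref_pos < aln.r_end):
        return None
    if aln.n_gap == 0:
        return aln.q_start + (ref_pos - aln.r_start)
    # walk is unnecessary for gapless amplicon alignments; for gapped ones
    # fall back to the proportional offset only when unambiguous
    return None


def nqs_call(read: Read, read_pos: int, strict: bool = False) -> bool:
    """Neighborhood Quality Standard at one read position: Phred >= 30 at
    the base and >= 20 at the 5 bases on either side.  In strict mode a
    position lacking 5 flanks on either side fails."""
    q = read.qual
    if q[read_pos] < NQS_SITE_Q:
        return False
    lo = read_pos - NQS_FLANK_N
    hi = read_pos + NQS_FLANK_N
    if strict and (lo < 0 or hi >= len(q)):
        return False
    for p in range(max(0, lo), min(len(q), hi + 1)):
        if p == read_pos:
            continue
        if q[p] < NQS_FLANK_Q:
            return False
    return True


def call_read(
    read: Read,
    target_ref: str,
    target_pos: int,
    expected_alt: str,
    params: AlignParams = DEFAULT_PARAMS,
    strict_nqs: bool = False,
) -> EditCall:
    """Full per-read call at the target position."""
    call = EditCall(read_id=read.read_id)
    if not read_qc(read):
        return call
    aln = best_local_alignment(read.seq, target_ref, params, both_strands=False)
    if not alignment_qc(aln):
        return call
    call.pass_read_filters = True
    call.aligned_len = aln.q_len
    rp = _read_pos_of_ref(aln, target_pos)
    if rp is None:
        return call
    call.read_base = read.seq[rp]
    call.ref_base = target_ref[target_pos]
    call.phred = read.qual[rp]
    if call.read_base != call.ref_base:
        call.nqs_pass = nqs_call(read, rp, strict=strict_nqs)
        call.edited_at_target = call.nqs_pass and call.read_base == expected_alt
    return call


@dataclass
class EfficiencyResult:
    n_pass: int
    n_edited: int
    efficiency: float | None  # percent, None when no pass-filter reads
    calls: list[EditCall] = field(default_factory=list)


def editing_efficiency(
    reads: list[Read],
    target_ref: str,
    target_pos: int,
    expected_alt: str,
    params: AlignParams = DEFAULT_PARAMS,
    strict_nqs: bool = False,
) -> EfficiencyResult:
    """Editing efficiency over a read set (or any subset, e.g. only
    insertion-bearing reads): 100 x edited / pass-filter.  NA (None) when
    no read passes the filters."""
    calls = [
        call_read(r, target_ref, target_pos, expected_alt, params, strict_nqs)
        for r in reads
    ]
    n_pass = sum(c.pass_read_filters for c in calls)
    n_edited = sum(c.edited_at_target for c in calls)
    eff = 100.0 * n_edited / n_pass if n_pass else None
    return EfficiencyResult(n_pass=n_pass, n_edited=n_edited, efficiency=eff, calls=calls)
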