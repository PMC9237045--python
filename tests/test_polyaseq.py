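"""PolyA-seq junction calling: artifact filters, dedup, poly(A) measure."""

import numpy as np
import pytest

from retrojoin.align import revcomp
from retrojoin.polyaseq import (
    PolyAJunction,
    call_junctions,
    dedup_pcr_repeats,
    default_ligation_predicate,
    filter_alignments,
    flag_ligation_artifacts,
    measure_polya,
)
from retrojoin.readprep import Read, filter_polyaseq_by_primer
from retrojoin.simulate import DEFAULT_POLYA_BARCODE, POLYA_NESTED_PRIMER


def _clean_pos(genome, chrom, start, length=120, forbid_leading_a=True):
    """A junction position whose flank is safely unique and A-poor at the
    boundary (so alignment edges match construction exactly)."""
    g = genome[chrom]
    p = start
    while True:
        if g[p - 1] != "A" and g[p] != "A" and "GGCC" != g[p - 2 : p + 2]:
            return p
        p += 1


PREFIX = DEFAULT_POLYA_BARCODE + POLYA_NESTED_PRIMER


def _read(rid, tail, flank):
    seq = PREFIX + "A" * tail + flank
    return Read(rid, seq, [35] * len(seq))


def build_filter_fixture(refset):
    """Twelve hand-built reads covering each PolyA-seq defect class."""
    g = refset.genome
    chrom = refset.target_chrom
    seq = g[chrom]
    p_good = _clean_pos(g, chrom, 30_000)
    p_rep = _clean_pos(g, chrom, 33_000)
    p_rep2 = _clean_pos(g, chrom, 36_000)
    p_score = _clean_pos(g, chrom, 39_000)
    p_gap = _clean_pos(g, chrom, 42_000)
    p_minus = _clean_pos(g, chrom, 48_000)
    while seq[p_minus - 1] == "T" or seq[p_minus] == "T":
        p_minus = _clean_pos(g, chrom, p_minus + 1)
    ggcc = seq.find("GGCC", 50_000)
    p_hae = ggcc + 2  # junction exactly at the blunt GG|CC boundary
    dup = next(si for si in refset.shared_intervals if si.ref_a in g)
    d0 = dup.interval_a[0]

    reads = [
        # 1: barcode but no primer -> removed by the primer filter
        Read("no_primer", DEFAULT_POLYA_BARCODE + "ACGT" * 38, [35] * 160),
        # 2: only 14 A's after the primer -> fails the 7+8 rule
        _read("tail14", 14, seq[p_good : p_good + 120]),
        # 3: clean survivor, plus strand
        _read("good_plus", 25, seq[p_good : p_good + 120]),
        # 4: junction at a HaeIII GG|CC boundary -> ligation artifact
        _read("haeiii", 25, seq[p_hae : p_hae + 120]),
        # 5+6: PCR-repeat pair, same junction, read starts 2 apart
        _read("rep_a", 25, seq[p_rep : p_rep + 120]),
        _read("rep_b", 27, seq[p_rep : p_rep + 118]),
        # 7+8: same junction, read starts 3 apart -> both kept
        _read("indep_a", 25, seq[p_rep2 : p_rep2 + 120]),
        _read("indep_b", 28, seq[p_rep2 : p_rep2 + 117]),
        # 9: 29-bp flank -> alignment score 29 < 30
        _read("score29", 25, seq[p_score : p_score + 29]),
        # 10: flank from the duplicated segment -> ambiguous placement
        _read("ambig", 25, seq[d0 + 300 : d0 + 420]),
        # 11: flank with an internal 10-nt deletion -> gapped alignment
        _read("gapped", 25, seq[p_gap : p_gap + 55] + seq[p_gap + 65 : p_gap + 130]),
        # 12: clean survivor, minus strand
        _read("good_minus", 25, revcomp(seq[p_minus - 120 : p_minus])),
    ]
    expected_kept = {"good_plus", "rep_a", "indep_a", "indep_b", "good_minus"}
    return reads, expected_kept


def test_filter_fixture_survivors_and_flags(refset, genome_index):
    reads, expected_kept = build_filter_fixture(refset)
    kept, dropped = filter_polyaseq_by_primer(reads, POLYA_NESTED_PRIMER)
    assert {r.read_id for r in dropped} == {"no_primer", "tail14"}
    junctions = call_junctions(
        [(r.read_id, r.seq) for r in kept], genome_index, refset.genome
    )
    by_id = {j.read_id: j for j in junctions}
    assert {j.read_id for j in junctions if j.reported} == expected_kept
    assert "ligation_artifact" in by_id["haeiii"].filter_flags
    assert "pcr_repeat" in by_id["rep_b"].filter_flags
    assert "low_score" in by_id["score29"].filter_flags
    assert "ambiguous" in by_id["ambig"].filter_flags
    assert "gapped" in by_id["gapped"].filter_flags
    # surviving calls carry the constructed positions and tails
    assert by_id["good_plus"].polya_len == 25
    assert by_id["good_minus"].strand == "-"


def test_filter_flags_are_order_independent(refset, genome_index):
    reads, _ = build_filter_fixture(refset)
    kept, _ = filter_polyaseq_by_primer(reads, POLYA_NESTED_PRIMER)
    pairs = [(r.read_id, r.seq) for r in kept]
    fwd = {j.read_id: frozenset(j.filter_flags) for j in call_junctions(pairs, genome_index, refset.genome)}
    rev = {j.read_id: frozenset(j.filter_flags) for j in call_junctions(pairs[::-1], genome_index, refset.genome)}
    assert fwd == rev


def _jx(rid, pos, start, chrom="chr1", strand="+"):
    return PolyAJunction(read_id=rid, chrom=chrom, pos=pos, strand=strand, read_aln_start=start)


def test_dedup_boundary_two_vs_three_bp():
    a, b = _jx("a", 100, 50), _jx("b", 100, 52)
    dedup_pcr_repeats([a, b])
    assert not a.filter_flags and b.filter_flags == {"pcr_repeat"}
    c, d = _jx("c", 100, 50), _jx("d", 100, 53)
    dedup_pcr_repeats([c, d])
    assert not c.filter_flags and not d.filter_flags
    e, f = _jx("e", 100, 50), _jx("f", 200, 51)
    dedup_pcr_repeats([e, f])
    assert not e.filter_flags and not f.filter_flags


def test_ligation_predicate_boundary(refset):
    g = refset.genome
    chrom = refset.target_chrom
    pos = g[chrom].find("GGCC", 20_000) + 2
    assert default_ligation_predicate(g, chrom, pos) is True
    assert not default_ligation_predicate(g, chrom, pos - 1)
    assert not default_ligation_predicate(g, chrom, pos + 1)
    assert default_ligation_predicate(g, chrom, 1) is None  # contig edge: pass
    j = _jx("x", pos, 0, chrom=chrom)
    flag_ligation_artifacts(j, g)
    assert j.filter_flags == {"ligation_artifact"}


def test_score_difference_of_exactly_four_is_kept():
    from retrojoin.align import Alignment

    mk = lambda s: Alignment(0, 40, 0, 40, s, "+", "chr1")
    assert "ambiguous" not in filter_alignments([mk(45), mk(41)])  # diff 4 kept
    assert "ambiguous" in filter_alignments([mk(45), mk(42)])  # diff 3 flagged
    assert "low_score" in filter_alignments([mk(29)])
    assert filter_alignments([mk(45)]) == set()


def test_measure_polya_rules():
    flank = "CGTCGTCGTTGCGTTGCC" * 3
    read = "N" * 28 + "A" * 25 + flank
    assert measure_polya(read, genomic_q_start=53) == 25
    short = "N" * 28 + "A" * 10 + flank
    assert measure_polya(short, genomic_q_start=38) == 0  # <11 ignored
    # A-run after the genomic segment: ordering constraint fails
    misordered = "N" * 28 + flank + "A" * 25
    assert measure_polya(misordered, genomic_q_start=28) == 0
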