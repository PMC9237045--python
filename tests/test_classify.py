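"""Source attribution rules, redundancy collapse, fragment maps."""

import copy

import numpy as np
import pytest

from retrojoin.align import revcomp
from retrojoin.classify import (
    InsertionRecord,
    align_to_references,
    attribute_source,
    build_fragment_map,
    classify_inserts,
    collapse_redundant,
    summarize_sources,
)
from retrojoin.simulate import (
    GENOMIC,
    L1HS,
    L1_REPORTER,
    PEGRNA,
    PLASMID_LENTI,
    UNCLASSIFIED,
)


def _attr(insert, refset, ref_index):
    alns = align_to_references(insert, refset, ref_index)
    return attribute_source(alns, refset)


def test_reporter_insert_plus_and_minus(refset, ref_index):
    frag = refset.reporter[3000:3060]  # inside codon-optimized ORF2
    label, aln, _ = _attr(frag, refset, ref_index)
    assert label == L1_REPORTER
    assert aln.orientation == "+"
    assert (aln.r_start, aln.r_end) == (3000, 3060)
    label, aln, _ = _attr(revcomp(frag), refset, ref_index)
    assert label == L1_REPORTER
    assert aln.orientation == "-"
    assert (aln.r_start, aln.r_end) == (3000, 3060)


def test_shared_vector_element_attributed_to_lenti_plasmid(refset, ref_index):
    si = refset.shared_for("reporter", "plasmid_lenti")[0]
    frag = refset.reporter[si.interval_a[0] + 20 : si.interval_a[0] + 80]
    label, _, _ = _attr(frag, refset, ref_index)
    assert label == PLASMID_LENTI


def test_l1hs_homologous_element_attributed_to_l1hs(refset, ref_index):
    si = refset.shared_for("reporter", "l1hs")[0]
    frag = refset.reporter[si.interval_a[0] + 10 : si.interval_a[0] + 70]
    label, _, _ = _attr(frag, refset, ref_index)
    assert label == L1HS
    # unique L1Hs sequence is attributed directly
    label, _, _ = _attr(refset.l1hs[500:560], refset, ref_index)
    assert label == L1HS


def test_pegrna_scaffold_hit_labelled_pegrna(refset, ref_index):
    p0, p1 = refset.pegrna_interval
    frag = refset.plasmid_editor[p0 : p0 + 40]
    label, _, _ = _attr(frag, refset, ref_index)
    assert label == PEGRNA


def test_genomic_requires_unambiguous_placement(refset, ref_index):
    g = refset.genome[refset.target_chrom]
    dup = next(si for si in refset.shared_intervals if si.ref_a in refset.genome)
    amb = g[dup.interval_a[0] + 200 : dup.interval_a[0] + 260]
    label, _, mapq_pass = _attr(amb, refset, ref_index)
    assert not mapq_pass
    assert label == UNCLASSIFIED
    uniq = g[45_000:45_060]
    label, _, mapq_pass = _attr(uniq, refset, ref_index)
    assert label == GENOMIC and mapq_pass


def test_unalignable_insert_is_unclassified(refset, ref_index):
    label, aln, _ = _attr("ACGT" * 10, refset, ref_index)
    # a generic repeat scores below the minimal reportable score everywhere
    assert label == UNCLASSIFIED or aln.score >= 30


def _rec(rid, start, end, source=L1_REPORTER, ref="reporter"):
    return InsertionRecord(
        read_id=rid, source=source, ref_name=ref, source_interval=(start, end), insert_len=end - start
    )


def test_collapse_merges_within_four_bp():
    recs = [_rec("a", 100, 400), _rec("b", 102, 403)]
    out = collapse_redundant(recs)
    assert len(out) == 1 and out[0].count == 2


def test_collapse_boundary_at_exactly_four_bp():
    recs = [_rec("a", 100, 400), _rec("b", 104, 403)]
    out = collapse_redundant(recs)
    assert len(out) == 2


def test_collapse_idempotent_and_single_record_unchanged():
    rng = np.random.default_rng(0)
    recs = [
        _rec(f"r{i}", int(s), int(s) + int(l))
        for i, (s, l) in enumerate(zip(rng.integers(0, 500, 40), rng.integers(50, 300, 40)))
    ]
    once = collapse_redundant(copy.deepcopy(recs))
    twice = collapse_redundant(copy.deepcopy(once))
    assert [(r.source_interval, r.count) for r in once] == [
        (r.source_interval, r.count) for r in twice
    ]
    assert collapse_redundant([_rec("solo", 10, 90)])[0].count == 1


def test_fragment_map_center_rule_and_empty(refset):
    rec = _rec("a", 3000, 3400)
    fmap = build_fragment_map([rec], refset, "reporter")
    assert fmap.center_counts[3200 // 100] == 1
    assert fmap.center_counts.sum() == 1
    assert fmap.coverage[30:34].tolist() == [1, 1, 1, 1]
    empty = build_fragment_map([], refset, "reporter")
    assert empty.coverage.sum() == 0 and empty.center_counts.sum() == 0


def test_summarize_sources_proportions_and_empty():
    recs = [_rec("a", 0, 100)] * 3 + [_rec("b", 0, 100, source=GENOMIC, ref="chr1")]
    s = summarize_sources(recs)
    assert abs(s[L1_REPORTER] - 0.75) < 1e-12
    assert abs(sum(v for k, v in s.items() if k != "unclassified_count") - 1.0) < 1e-12
    assert summarize_sources([]) == {"unclassified_count": 0}
    only_uncl = [InsertionRecord("x", UNCLASSIFIED)]
    assert summarize_sources(only_uncl)["unclassified_count"] == 1
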