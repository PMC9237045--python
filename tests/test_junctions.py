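"""Junction microhomology/gap determination and validity filters."""

import numpy as np
import pytest

from retrojoin.align import revcomp
from retrojoin.junctions import (
    JunctionRecord,
    Rejection,
    junction_for_side,
    mh_histogram,
    pegrna_junction,
)
from retrojoin.simulate import construct_junction_case


def _run(case):
    return junction_for_side(
        "r", case.read_seq, case.target_ref, case.insert_ref, case.side, case.cut_site_ref
    )


@pytest.mark.parametrize("side", ["left", "right"])
@pytest.mark.parametrize("orientation", ["+", "-"])
@pytest.mark.parametrize("mh,gap", [(0, 0), (4, 0), (10, 0), (0, 1), (0, 12)])
def test_constructed_junctions_recovered_exactly(side, orientation, mh, gap):
    rng = np.random.default_rng(hash((side, orientation, mh, gap)) % 2**31)
    case = construct_junction_case(rng, side, orientation, mh, gap)
    rec = _run(case)
    assert isinstance(rec, JunctionRecord), getattr(rec, "reason", None)
    assert (rec.mh_len, rec.gap_len) == (mh, gap)
    assert rec.orientation == orientation
    assert rec.junction_offset == 0
    assert rec.gap_label == ("other_sources" if gap else "none")


def test_direct_joint_has_no_gap_label():
    rng = np.random.default_rng(0)
    rec = _run(construct_junction_case(rng, "left", "+", 0, 0))
    assert rec.mh_len == 0 and rec.gap_len == 0 and rec.gap_label == "none"


def test_target_alignment_must_start_near_read_end():
    rng = np.random.default_rng(1)
    case = construct_junction_case(rng, "left", "+", 3, 0)
    junk = "GT" * 10
    rec = junction_for_side(
        "r", junk[:9] + case.read_seq, case.target_ref, case.insert_ref, "left", case.cut_site_ref
    )
    assert isinstance(rec, Rejection) and rec.reason == "target_start_too_far"
    rec = junction_for_side(
        "r", junk[:8] + case.read_seq, case.target_ref, case.insert_ref, "left", case.cut_site_ref
    )
    assert isinstance(rec, JunctionRecord) and rec.mh_len == 3


def test_short_target_alignment_rejected():
    rng = np.random.default_rng(2)
    ok = construct_junction_case(rng, "left", "+", 0, 0, flank_len=18)
    assert isinstance(_run(ok), JunctionRecord)
    short = construct_junction_case(rng, "left", "+", 0, 0, flank_len=17)
    rec = _run(short)
    assert isinstance(rec, Rejection) and rec.reason == "target_alignment_too_short"


def test_short_insert_alignment_rejected():
    rng = np.random.default_rng(3)
    ok = construct_junction_case(rng, "left", "+", 0, 0, insert_len=30)
    assert isinstance(_run(ok), JunctionRecord)
    short = construct_junction_case(rng, "left", "+", 0, 0, insert_len=29)
    rec = _run(short)
    assert isinstance(rec, Rejection) and rec.reason == "insert_alignment_too_short"


def test_insert_contained_in_target_rejected():
    rng = np.random.default_rng(4)
    case = construct_junction_case(rng, "left", "+", 0, 0)
    # use the flank itself as the "insert" reference: fully contained
    rec = junction_for_side(
        "r", case.read_seq, case.target_ref, case.target_ref[:80], "left", case.cut_site_ref
    )
    assert isinstance(rec, Rejection) and rec.reason == "insert_contained_in_target"


def _pegrna_read(rng, refset, peg_span, with_edit=True, orientation="-"):
    lo, locus = refset.target_locus[0], None
    g = refset.genome[refset.target_chrom]
    target_ref = g[refset.cut_site - 200 : refset.cut_site + 200]
    j = 200
    scaffold = refset.pegrna_scaffold
    s0, s1 = peg_span
    piece = scaffold[s0:s1]
    insert = revcomp(piece) if orientation == "-" else piece
    read = target_ref[:j] + insert + "G" * 10
    edited_pos = (s0 + s1) // 2 if with_edit else -1
    return read, target_ref, scaffold, edited_pos, j


def test_pegrna_junction_rules(refset):
    rng = np.random.default_rng(5)
    read, target_ref, scaffold, pos, j = _pegrna_read(rng, refset, (10, 50))
    rec = pegrna_junction("r", read, target_ref, scaffold, pos, "left", j)
    assert isinstance(rec, JunctionRecord)
    assert rec.orientation == "-"
    # plus orientation rejected
    read_p, _, _, pos_p, _ = _pegrna_read(rng, refset, (10, 50), orientation="+")
    rec = pegrna_junction("r", read_p, target_ref, scaffold, pos_p, "left", j)
    assert isinstance(rec, Rejection) and rec.reason == "pegrna_plus_orientation"
    # 9-bp scaffold match rejected
    read_9, _, _, pos_9, _ = _pegrna_read(rng, refset, (10, 19))
    rec = pegrna_junction("r", read_9, target_ref, scaffold, pos_9, "left", j)
    assert isinstance(rec, Rejection)
    # edited base outside the aligned scaffold portion rejected
    rec = pegrna_junction("r", read, target_ref, scaffold, 80, "left", j)
    assert isinstance(rec, Rejection) and rec.reason == "pegrna_missing_edited_base"


def test_mh_histogram_conserves_counts():
    recs = [
        JunctionRecord("a", "left", mh_len=3),
        JunctionRecord("b", "left", mh_len=3),
        JunctionRecord("c", "left", gap_len=7),
        JunctionRecord("d", "right", orientation="-", mh_len=0),
    ]
    hist = mh_histogram(recs)
    assert hist[("left", "+")][3] == 2
    assert hist[("left", "+")][-1] == 1  # "other sources" gap junction
    assert hist[("right", "-")][0] == 1
    assert sum(v for h in hist.values() for v in h.values()) == len(recs)
    assert mh_histogram([]) == {}
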