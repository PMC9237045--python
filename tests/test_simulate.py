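"""Synthetic-data generator: determinism, truth invariants, structure."""

import numpy as np
import pytest

from retrojoin.io import write_fastq, write_paired_fastq
from retrojoin.simulate import (
    DEFAULT_FWD_BARCODE,
    DEFAULT_POLYA_BARCODE,
    DEFAULT_REV_BARCODE,
    EditSpec,
    GENOMIC,
    L1_REPORTER,
    PLASMID_LENTI,
    POLYA_NESTED_PRIMER,
    SimulationConfig,
    default_amplicon_design,
    point_mass,
    simulate_amplicon_reads,
    simulate_edited_reads,
    simulate_insertion_events,
    simulate_polyaseq_reads,
)


def _events(refset, **kw):
    cfg = SimulationConfig(**{"seed": 11, "n_reads": 60, "error_rate": 0.0, **kw})
    return simulate_insertion_events(refset, cfg), cfg


def test_config_validation_rejects_bad_mixture():
    with pytest.raises(ValueError):
        SimulationConfig(source_mixture={L1_REPORTER: 0.7, GENOMIC: 0.2})
    with pytest.raises(ValueError):
        SimulationConfig(error_rate=1.5)


def test_events_deterministic_for_seed(refset):
    ev1, _ = _events(refset)
    ev2, _ = _events(refset)
    assert [e.edited_locus for e in ev1] == [e.edited_locus for e in ev2]
    ev3, _ = _events(refset, seed=12)
    assert [e.edited_locus for e in ev1] != [e.edited_locus for e in ev3]


def test_truth_invariants_hold(refset):
    events, _ = _events(refset, n_reads=120)
    for e in events:
        t = e.truth
        t.check_invariants()
        assert not (t.true_mh_left and t.true_gap_left)
        assert not (t.true_mh_right and t.true_gap_right)
        assert t.true_insert_interval[0] < t.true_insert_interval[1]


def test_mixture_proportions_converge(refset):
    mixture = {L1_REPORTER: 0.5, PLASMID_LENTI: 0.25, GENOMIC: 0.25}
    events, cfg = _events(refset, n_reads=2000, source_mixture=mixture)
    n = len(events)
    for src, p in mixture.items():
        k = sum(e.truth.true_source == src for e in events)
        sigma = (n * p * (1 - p)) ** 0.5
        assert abs(k - n * p) <= 3 * sigma


def test_spliced_inserts_never_contain_intron_sequence(refset):
    events, _ = _events(
        refset, source_mixture={L1_REPORTER: 1.0}, splice_fraction=1.0, n_reads=40
    )
    i0, i1 = refset.intron
    probe = refset.reporter[i0 + 10 : i0 + 50]
    for e in events:
        assert e.truth.true_spliced
        assert probe not in e.insert_seq
        from retrojoin.align import revcomp

        assert revcomp(probe) not in e.insert_seq


def test_unspliced_long_inserts_do_contain_intron(refset):
    events, _ = _events(
        refset, source_mixture={L1_REPORTER: 1.0}, splice_fraction=0.0, n_reads=60
    )
    i0, i1 = refset.intron
    probe = refset.reporter[i0 + 10 : i0 + 50]
    long_enough = [
        e for e in events if e.truth.true_insert_interval[0] < i0
    ]
    assert long_enough
    from retrojoin.align import revcomp

    for e in long_enough:
        assert probe in e.insert_seq or revcomp(probe) in e.insert_seq


def test_reporter_inserts_anchor_at_cassette_three_prime_end(refset):
    events, _ = _events(refset, source_mixture={L1_REPORTER: 1.0}, n_reads=40)
    for e in events:
        assert e.truth.true_insert_interval[1] == len(refset.reporter)


def test_point_mass_microhomology_planted(refset):
    events, _ = _events(
        refset,
        mh_distribution=point_mass(3),
        gap_fraction=0.0,
        source_mixture={PLASMID_LENTI: 1.0},
        n_reads=40,
    )
    for e in events:
        assert 3 in (e.truth.true_mh_left, e.truth.true_mh_right)


def test_genomic_inserts_stay_within_dsb_window(refset):
    events, _ = _events(
        refset, source_mixture={GENOMIC: 1.0}, dsb_window=5000, n_reads=60
    )
    for e in events:
        lo, hi = e.truth.true_insert_interval
        assert refset.cut_site - 5000 <= lo and hi <= refset.cut_site + 5000


def test_amplicon_reads_structure_and_determinism(refset, tmp_path):
    events, cfg = _events(refset, n_reads=30)
    design = default_amplicon_design(refset)
    pairs, truths = simulate_amplicon_reads(
        events, design, DEFAULT_FWD_BARCODE, DEFAULT_REV_BARCODE, cfg
    )
    assert len(pairs) == len(truths) == 30
    for pair, ev in zip(pairs, events):
        assert pair.r1.seq.startswith(DEFAULT_FWD_BARCODE + design.fwd_primer)
        assert pair.r2.seq.startswith(DEFAULT_REV_BARCODE + design.rev_primer)
        # error-free reads are exact substrings of the edited locus
        assert pair.r1.seq[len(DEFAULT_FWD_BARCODE):] in ev.edited_locus
    pairs2, _ = simulate_amplicon_reads(
        events, design, DEFAULT_FWD_BARCODE, DEFAULT_REV_BARCODE, cfg
    )
    p1, p2 = tmp_path / "a1.fastq", tmp_path / "a2.fastq"
    write_paired_fastq(pairs, p1, tmp_path / "b1.fastq")
    write_paired_fastq(pairs2, p2, tmp_path / "b2.fastq")
    assert p1.read_bytes() == p2.read_bytes()


def test_polyaseq_en_dependent_reads_sit_at_planted_nicks(refset):
    cfg = SimulationConfig(seed=5, n_reads=50, error_rate=0.0, en_dependent_fraction=1.0)
    reads, truths = simulate_polyaseq_reads(
        refset, cfg, DEFAULT_POLYA_BARCODE, POLYA_NESTED_PRIMER
    )
    nicks = {(m.chrom, m.nick_pos) for m in refset.motif_sites}
    for t in truths:
        assert (t.true_chrom, t.true_junction_pos) in nicks
        assert t.true_junction_call == t.true_junction_pos


def test_polyaseq_en_independent_reads_stay_near_cut(refset):
    cfg = SimulationConfig(seed=5, n_reads=50, error_rate=0.0, en_dependent_fraction=0.0)
    _, truths = simulate_polyaseq_reads(
        refset, cfg, DEFAULT_POLYA_BARCODE, POLYA_NESTED_PRIMER
    )
    for t in truths:
        assert t.true_chrom == refset.target_chrom
        assert abs(t.true_junction_pos - refset.cut_site) <= 5000


def test_polyaseq_point_mass_tail(refset):
    cfg = SimulationConfig(
        seed=6, n_reads=30, error_rate=0.0, polya_distribution=point_mass(20)
    )
    reads, truths = simulate_polyaseq_reads(
        refset, cfg, DEFAULT_POLYA_BARCODE, POLYA_NESTED_PRIMER
    )
    prefix = DEFAULT_POLYA_BARCODE + POLYA_NESTED_PRIMER
    for r, t in zip(reads, truths):
        assert r.seq.startswith(prefix + "A" * 20)
        assert t.true_polya_len >= 20


def test_edited_reads_truth_fraction_and_nqs_planting(refset):
    spec = EditSpec(position=refset.cut_site - 6, alt_base="T")
    g = refset.genome[refset.target_chrom]
    if g[spec.position] == "T":
        spec = EditSpec(position=spec.position, alt_base="C")
    cfg = SimulationConfig(seed=8, n_reads=100, error_rate=0.0)
    _, truths, _ = simulate_edited_reads(refset, spec, cfg, edited_fraction=0.37)
    assert sum(t.true_edit == "edited" for t in truths) == 37
    assert all(t.true_nqs_callable for t in truths if t.true_edit == "edited")
    _, truths_q25, _ = simulate_edited_reads(
        refset, spec, cfg, edited_fraction=0.37, site_quality=25
    )
    assert not any(t.true_nqs_callable for t in truths_q25)
    _, truths_b, _ = simulate_edited_reads(refset, spec, cfg, edited_fraction=0.37)
    assert [t.true_edit for t in truths] == [t.true_edit for t in truths_b]
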