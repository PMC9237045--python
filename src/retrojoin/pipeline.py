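"""End-to-end drivers composing the analysis stages, with audit logging.

Every stage reports how many reads it discarded; the audit obeys strict
count conservation (input = discarded-per-stage + survivors).  All
randomness in a run flows from the single simulation seed; given the same
inputs the pipelines are deterministic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .align import GenomeIndex, revcomp
from .classify import (
    InsertionRecord,
    classify_inserts,
    collapse_redundant,
    reference_index,
    summarize_sources,
)
from .io import write_bed, write_manifest, write_tsv
from .junctions import JunctionRecord, Rejection, junction_for_side, mh_histogram
from .motif import PWMWindow, window_scores
from .polyaseq import PolyAJunction, call_junctions
from .readprep import (
    ReadPair,
    Read,
    SampleSheet,
    collapse_pcr_duplicates,
    demultiplex_pairs,
    demultiplex_reads,
    drop_short_inserts,
    expected_downstream,
    filter_amplicon_by_primer,
    filter_polyaseq_by_primer,
    trim_insert_portion,
)
from .refs import ReferenceSet
from .simulate import AmpliconDesign, UNCLASSIFIED, default_amplicon_design, locus_window


@dataclass
class PipelineConfig:
    """All tunable thresholds, with the analysis defaults: 30-bp minimum
    insert, alignment score 30, ambiguity score difference 4, 10-nt gap
    limit, <3 bp PCR-repeat window, <4 bp redundancy collapse, -3..+8
    motif flank, 30-insertion windows, NQS 30/20, read QC mean Q20 /
    length 50 / aligned 80, poly(A) minimum 11, primer+7A+8A filter."""

    seed: int = 0
    dialect: str = "amplicon"
    min_insert_len: int = 30
    min_align_score: int = 30
    ambig_score_diff: int = 4
    max_alignment_gap: int = 10
    pcr_repeat_delta: int = 3
    collapse_delta: int = 4
    flank_window: tuple[int, int] = (3, 8)
    motif_window_size: int = 30
    nqs: tuple[int, int] = (30, 20)
    read_qc: tuple[float, int, int] = (20.0, 50, 80)
    min_polya: int = 11
    polya_primer_rule: tuple[int, int] = (7, 8)


@dataclass
class SampleAmpliconResult:
    sample: str
    audit: dict[str, int]
    records: list[InsertionRecord]
    collapsed: list[InsertionRecord]
    summary: dict[str, float]
    junctions: list[JunctionRecord]
    rejections: list[Rejection]
    mh_hist: dict


@dataclass
class AmpliconResult:
    n_input: int
    n_unassigned: int
    samples: dict[str, SampleAmpliconResult] = field(default_factory=dict)


def run_amplicon_pipeline(
    refset: ReferenceSet,
    pairs: list[ReadPair],
    sheet: SampleSheet,
    design: AmpliconDesign | None = None,
    ref_index: GenomeIndex | None = None,
) -> AmpliconResult:
    """demux -> primer filter -> trim -> dedup -> classify -> junctions."""
    design = design or default_amplicon_design(refset)
    lo, locus = locus_window(refset)
    cut_local = refset.cut_site - lo
    locus_rc = revcomp(locus)
    if ref_index is None:
        ref_index = reference_index(refset)

    assigned, unassigned = demultiplex_pairs(pairs, sheet)
    result = AmpliconResult(n_input=len(pairs), n_unassigned=len(unassigned))
    for spec in sheet.samples:
        if spec.dialect != "amplicon":
            continue
        sample_pairs = assigned.get(spec.name, [])
        kept, dropped = filter_amplicon_by_primer(
            sample_pairs,
            spec.fwd_primer,
            expected_downstream(locus, spec.fwd_primer),
            spec.rev_primer,
            expected_downstream(locus_rc, spec.rev_primer),
        )
        by_id = {p.read_id: p for p in kept}
        inserts = []
        n_no_insert = 0
        for p in kept:
            ins = trim_insert_portion(p.r1.seq, locus, spec.fwd_primer)
            if ins:
                inserts.append((p.read_id, ins))
            else:
                n_no_insert += 1
        n0 = len(inserts)
        inserts = collapse_pcr_duplicates(inserts)
        n_dup = n0 - len(inserts)
        n1 = len(inserts)
        inserts = drop_short_inserts(inserts)
        n_short = n1 - len(inserts)

        records = classify_inserts(inserts, refset, ref_index)
        collapsed = collapse_redundant(records)
        summary = summarize_sources(collapsed)

        junctions: list[JunctionRecord] = []
        rejections: list[Rejection] = []
        for rec in records:
            if rec.source == UNCLASSIFIED:
                continue
            pair = by_id.get(rec.read_id)
            if pair is None:
                continue
            for side, seq in (("left", pair.r1.seq), ("right", pair.r2.seq)):
                oriented = seq if side == "left" else revcomp(seq)
                i_hits = [
                    h for h in ref_index.align(oriented) if h.ref_name == rec.ref_name
                ]
                res = junction_for_side(
                    rec.read_id, seq, locus, None, side, cut_local,
                    insert_source=rec.source,
                    insert_candidates=i_hits,
                )
                (junctions if isinstance(res, JunctionRecord) else rejections).append(res)

        audit = {
            "assigned": len(sample_pairs),
            "primer_filtered": len(dropped),
            "no_insert": n_no_insert,
            "pcr_duplicates": n_dup,
            "short_inserts": n_short,
            "classified_inserts": len(records),
        }
        result.samples[spec.name] = SampleAmpliconResult(
            sample=spec.name,
            audit=audit,
            records=records,
            collapsed=collapsed,
            summary=summary,
            junctions=junctions,
            rejections=rejections,
            mh_hist=mh_histogram(junctions),
        )
    return result


@dataclass
class SamplePolyASeqResult:
    sample: str
    audit: dict[str, int]
    junctions: list[PolyAJunction]
    reported: list[PolyAJunction]
    windows: dict[str, list[PWMWindow]]
    audit_log: pd.DataFrame


@dataclass
class PolyASeqResult:
    n_input: int
    n_unassigned: int
    samples: dict[str, SamplePolyASeqResult] = field(default_factory=dict)


def run_polyaseq_pipeline(
    refset: ReferenceSet,
    reads: list[Read],
    sheet: SampleSheet,
    genome_index: GenomeIndex | None = None,
    motif_window_size: int = 30,
) -> PolyASeqResult:
    """filter/mask -> seeded genome alignment -> artifact flags ->
    junction calls -> poly(A) measurement -> motif windows."""
    if genome_index is None:
        genome_index = GenomeIndex(refset.genome)
    assigned, unassigned = demultiplex_reads(reads, sheet)
    result = PolyASeqResult(n_input=len(reads), n_unassigned=len(unassigned))
    for spec in sheet.samples:
        if spec.dialect != "polyaseq":
            continue
        sample_reads = assigned.get(spec.name, [])
        kept, dropped = filter_polyaseq_by_primer(sample_reads, spec.fwd_primer)
        junctions = call_junctions(
            [(r.read_id, r.seq) for r in kept], genome_index, refset.genome
        )
        reported = [j for j in junctions if j.reported]

        windows: dict[str, list[PWMWindow]] = {}
        by_chrom: dict[str, list[tuple[int, str]]] = {}
        for j in reported:
            by_chrom.setdefault(j.chrom, []).append((j.pos, j.strand))
        for chrom, items in sorted(by_chrom.items()):
            items.sort()
            ws = window_scores(items, refset.genome, chrom, motif_window_size)
            if ws:
                windows[chrom] = ws

        log_rows = [
            {"read_id": j.read_id, "kept": j.reported,
             "flags": ",".join(sorted(j.filter_flags)) or "-"}
            for j in junctions
        ]
        audit = {
            "assigned": len(sample_reads),
            "primer_filtered": len(dropped),
            "flagged": len(junctions) - len(reported),
            "reported": len(reported),
        }
        result.samples[spec.name] = SamplePolyASeqResult(
            sample=spec.name,
            audit=audit,
            junctions=junctions,
            reported=reported,
            windows=windows,
            audit_log=pd.DataFrame(log_rows, columns=["read_id", "kept", "flags"]),
        )
    return result


def write_reports(
    result: AmpliconResult | PolyASeqResult,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> list[Path]:
    """Emit the TSV/BED report bundle plus a machine-readable manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str, bed: bool = False):
        path = out / name
        if bed:
            write_bed(df, path)
        else:
            write_tsv(df, path)
        written.append(path)

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config) if config else {},
        "n_input": result.n_input,
        "n_unassigned": result.n_unassigned,
    }
    if isinstance(result, AmpliconResult):
        for name, sr in sorted(result.samples.items()):
            emit(
                pd.DataFrame(
                    [
                        {
                            "read_id": r.read_id,
                            "source": r.source,
                            "ref": r.ref_name,
                            "start": r.source_interval[0],
                            "end": r.source_interval[1],
                            "orientation": r.orientation,
                            "count": r.count,
                        }
                        for r in sr.collapsed
                    ]
                ),
                f"{name}.fragments.tsv",
            )
            emit(
                pd.DataFrame(
                    [
                        {
                            "read_id": j.read_id,
                            "side": j.dsb_side,
                            "source": j.insert_source,
                            "orientation": j.orientation,
                            "mh_len": j.mh_len,
                            "gap_len": j.gap_len,
                            "junction_offset": j.junction_offset,
                        }
                        for j in sr.junctions
                    ]
                ),
                f"{name}.junctions.tsv",
            )
            emit(
                pd.DataFrame(
                    [{"stage": k, "count": v} for k, v in sr.audit.items()]
                ),
                f"{name}.audit.tsv",
            )
            manifest[f"summary:{name}"] = sr.summary
    else:
        for name, sr in sorted(result.samples.items()):
            emit(
                pd.DataFrame(
                    [
                        {
                            "chrom": j.chrom,
                            "start": j.pos,
                            "end": j.pos + 1,
                            "name": j.read_id,
                            "score": int(j.align_score),
                            "strand": j.strand,
                        }
                        for j in sr.reported
                    ]
                ),
                f"{name}.junctions.bed",
                bed=True,
            )
            emit(
                pd.DataFrame(
                    [
                        {"read_id": j.read_id, "polya_len": j.polya_len}
                        for j in sr.reported
                    ]
                ),
                f"{name}.polya.tsv",
            )
            emit(sr.audit_log, f"{name}.audit_log.tsv")
            emit(
                pd.DataFrame(
                    [
                        {
                            "chrom": chrom,
                            "center": w.center,
                            "span_start": w.region[0],
                            "span_end": w.region[1],
                            "n": w.n,
                            "motif_score": w.motif_score,
                        }
                        for chrom, ws in sorted(sr.windows.items())
                        for w in ws
                    ]
                ),
                f"{name}.window_scores.tsv",
            )
            manifest[f"audit:{name}"] = sr.audit
    mpath = out / "manifest.json"
    write_manifest(manifest, mpath)
    written.append(mpath)
    return written
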