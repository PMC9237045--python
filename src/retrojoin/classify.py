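"""Insertion-source attribution, redundancy collapse and fragment maps.

Each trimmed insert is aligned against every reference (reporter cassette,
L1Hs consensus, lentiviral and editor plasmids, and the genome through a
seeded index).  Attribution follows declarative priority rules driven by
the reference set's recorded shared intervals:

1. an insert whose reporter alignment lies in a sequence element shared
   with the lentiviral plasmid — and that the plasmid explains at least as
   well — is attributed to the plasmid;
2. likewise for elements shared with endogenous L1Hs;
3. otherwise the best-scoring reference wins (pegRNA-scaffold hits on the
   editor plasmid are labelled PEGRNA);
4. genomic attributions additionally require an unambiguous placement
   (best and runner-up separated by >= 4 score units, the mapq >= 2
   analogue); anything below the minimal score is UNCLASSIFIED.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import Alignment, AlignParams, DEFAULT_PARAMS, GenomeIndex
from .refs import ReferenceSet
from .simulate import (
    GENOMIC,
    L1HS,
    L1_REPORTER,
    PEGRNA,
    PLASMID_EDITOR,
    PLASMID_LENTI,
    UNCLASSIFIED,
)

MIN_ALIGN_SCORE = 30
MAPQ_SCORE_DIFF = 4


@dataclass
class InsertionRecord:
    read_id: str
    source: str
    orientation: str = "+"
    ref_name: str = ""
    source_interval: tuple[int, int] = (0, 0)
    insert_len: int = 0
    score: float = 0.0
    mapq_pass: bool = True
    count: int = 1


@dataclass
class FragmentMap:
    """Binned fragment map over one source reference (100-bp bins).

    ``coverage`` counts fragments overlapping each bin; ``center_counts``
    counts fragment centers per bin; both are stratified by orientation in
    ``by_orientation``.
    """

    ref_name: str
    ref_len: int
    bin_size: int
    coverage: np.ndarray
    center_counts: np.ndarray
    by_orientation: dict[str, np.ndarray] = field(default_factory=dict)
    n_fragments: int = 0


def reference_index(refset: ReferenceSet, k: int = 13) -> GenomeIndex:
    """Seeded k-mer index over every alignment reference (genome
    chromosomes, reporter, plasmids, L1Hs); built once per run."""
    return GenomeIndex(refset.reference_sequences(), k=k)


def align_to_references(
    insert: str,
    refset: ReferenceSet,
    index: GenomeIndex,
    params: AlignParams = DEFAULT_PARAMS,
) -> dict[str, Alignment | None]:
    """Best alignment of the insert against each reference, through the
    seeded index (windowed affine DP, identical scoring to local_align).

    The genome entry reports the best placement across chromosomes;
    ``genome_runner_up`` holds the second-best distinct placement for the
    mapping-quality proxy.
    """
    hits = index.align(insert, params)
    out: dict[str, Alignment | None] = {
        name: None
        for name in ("reporter", "l1hs", "plasmid_lenti", "plasmid_editor", "genome", "genome_runner_up")
    }
    chroms = set(refset.genome)
    for h in hits:  # hits are score-sorted, keep the best per reference
        if h.ref_name in chroms:
            if out["genome"] is None:
                out["genome"] = h
            elif out["genome_runner_up"] is None:
                out["genome_runner_up"] = h
        elif h.ref_name in out and out[h.ref_name] is None:
            out[h.ref_name] = h
    return out


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def attribute_source(
    alignments: dict[str, Alignment | None],
    refset: ReferenceSet,
    min_score: int = MIN_ALIGN_SCORE,
) -> tuple[str, Alignment | None, bool]:
    """Apply the priority rules; returns (label, winning alignment,
    mapq_pass).  ``mapq_pass`` is meaningful for genomic attributions."""
    rep = alignments.get("reporter")
    genome = alignments.get("genome")
    runner = alignments.get("genome_runner_up")
    mapq_pass = True
    if genome is not None and runner is not None:
        mapq_pass = (genome.score - runner.score) >= MAPQ_SCORE_DIFF

    def score(aln: Alignment | None) -> float:
        return aln.score if aln is not None else float("-inf")

    # shared-element exclusions take priority over raw best score
    if rep is not None and score(rep) >= min_score:
        rep_iv = (rep.r_start, rep.r_end)
        for si in refset.shared_for("reporter", "plasmid_lenti"):
            if _overlaps(rep_iv, si.interval_a) and score(
                alignments.get("plasmid_lenti")
            ) >= score(rep):
                return PLASMID_LENTI, alignments["plasmid_lenti"], mapq_pass
        for si in refset.shared_for("reporter", "l1hs"):
            if _overlaps(rep_iv, si.interval_a) and score(
                alignments.get("l1hs")
            ) >= score(rep):
                return L1HS, alignments["l1hs"], mapq_pass

    candidates = [
        (L1_REPORTER, rep),
        (L1HS, alignments.get("l1hs")),
        (PLASMID_LENTI, alignments.get("plasmid_lenti")),
        (PLASMID_EDITOR, alignments.get("plasmid_editor")),
        (GENOMIC, genome),
    ]
    candidates = [(lab, a) for lab, a in candidates if a is not None and a.score >= min_score]
    if not candidates:
        return UNCLASSIFIED, None, mapq_pass
    candidates.sort(key=lambda la: -la[1].score)
    for label, aln in candidates:
        if label == GENOMIC and not mapq_pass:
            continue
        if label == PLASMID_EDITOR and _overlaps(
            (aln.r_start, aln.r_end), refset.pegrna_interval
        ):
            return PEGRNA, aln, mapq_pass
        return label, aln, mapq_pass
    return UNCLASSIFIED, None, mapq_pass


def classify_inserts(
    inserts: list[tuple[str, str]],
    refset: ReferenceSet,
    index: GenomeIndex | None = None,
    params: AlignParams = DEFAULT_PARAMS,
    min_score: int = MIN_ALIGN_SCORE,
) -> list[InsertionRecord]:
    """Classify (read_id, insert_seq) pairs into InsertionRecords."""
    if index is None:
        index = reference_index(refset)
    records = []
    for read_id, ins in inserts:
        alns = align_to_references(ins, refset, index, params)
        label, aln, mapq_pass = attribute_source(alns, refset, min_score)
        if aln is None:
            records.append(
                InsertionRecord(read_id, UNCLASSIFIED, insert_len=len(ins), mapq_pass=mapq_pass)
            )
        else:
            records.append(
                InsertionRecord(
                    read_id=read_id,
                    source=label,
                    orientation=aln.orientation,
                    ref_name=aln.ref_name or label.lower(),
                    source_interval=(aln.r_start, aln.r_end),
                    insert_len=len(ins),
                    score=aln.score,
                    mapq_pass=mapq_pass,
                )
            )
    return records


def collapse_redundant(records: list[InsertionRecord]) -> list[InsertionRecord]:
    """Merge records of one source whose reference start AND end are each
    within <4 bp of an already-kept record (greedy over (start, end) order);
    the kept record accumulates the merged count.  Idempotent."""
    out: list[InsertionRecord] = []
    by_source: dict[tuple[str, str], list[InsertionRecord]] = {}
    for rec in records:
        if rec.source == UNCLASSIFIED:
            out.append(rec)
            continue
        by_source.setdefault((rec.source, rec.ref_name), []).append(rec)
    for key in sorted(by_source):
        group = sorted(by_source[key], key=lambda r: (r.source_interval, r.read_id))
        kept: list[InsertionRecord] = []
        for rec in group:
            merged = False
            for k in kept:
                if (
                    abs(rec.source_interval[0] - k.source_interval[0]) < 4
                    and abs(rec.source_interval[1] - k.source_interval[1]) < 4
                ):
                    k.count += rec.count
                    merged = True
                    break
            if not merged:
                kept.append(
                    InsertionRecord(**{**rec.__dict__})
                )
        out.extend(kept)
    return out


def build_fragment_map(
    records: list[InsertionRecord],
    refset: ReferenceSet,
    ref_name: str = "reporter",
    bin_size: int = 100,
) -> FragmentMap:
    """100-bp binned fragment map of one reference: per-bin overlap counts
    and fragment-center counts, stratified by orientation."""
    ref_len = len(refset.reference_sequences()[ref_name])
    n_bins = (ref_len + bin_size - 1) // bin_size
    cov = np.zeros(n_bins, dtype=int)
    centers = np.zeros(n_bins, dtype=int)
    by_orient = {"+": np.zeros(n_bins, dtype=int), "-": np.zeros(n_bins, dtype=int)}
    n = 0
    for rec in records:
        if rec.ref_name != ref_name or rec.source == UNCLASSIFIED:
            continue
        s, e = rec.source_interval
        s, e = max(0, s), min(ref_len, e)
        if e <= s:
            continue
        n += rec.count
        b0, b1 = s // bin_size, (e - 1) // bin_size
        cov[b0 : b1 + 1] += rec.count
        center_bin = ((s + e) // 2) // bin_size
        centers[center_bin] += rec.count
        if rec.orientation in by_orient:
            by_orient[rec.orientation][center_bin] += rec.count
    return FragmentMap(ref_name, ref_len, bin_size, cov, centers, by_orient, n)


def summarize_sources(records: list[InsertionRecord]) -> dict[str, float]:
    """Relative abundance of each source over classified records;
    UNCLASSIFIED is reported separately as ``unclassified_count``."""
    counts: dict[str, int] = {}
    n_uncl = 0
    for rec in records:
        if rec.source == UNCLASSIFIED:
            n_uncl += rec.count
            continue
        counts[rec.source] = counts.get(rec.source, 0) + rec.count
    total = sum(counts.values())
    out: dict[str, float] = {}
    if total:
        out = {src: counts[src] / total for src in sorted(counts)}
    out["unclassified_count"] = n_uncl
    return out
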