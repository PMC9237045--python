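"""Demultiplexing, primer filtering, masking and insert trimming.

Two assay dialects share this stage.  Amplicon libraries are paired-end:
each mate starts with a sample barcode followed by the locus PCR primer.
PolyA-seq libraries are single-end: barcode, nested primer, then the
captured poly(A) run and downstream genomic flank.

Demultiplexing uses an 8-bp key per mate: the barcode itself, padded with
the leading primer bases when the barcode is shorter than 8 bp.  Matching
is exact everywhere in this stage — the filters exist to enhance
specificity, so no mismatch tolerance is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

DEMUX_KEY_LEN = 8
MIN_INSERT_LEN = 30
POLYA_PRIMER_IMPOSED = 7  # A's appended directly to the nested primer
POLYA_ADDITIONAL = 8  # further A's required downstream


@dataclass
class Read:
    """Single-end read with per-base Phred qualities."""

    read_id: str
    seq: str
    qual: list[int]
    sample: str | None = None

    def __post_init__(self):
        if len(self.seq) != len(self.qual):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass
class ReadPair:
    read_id: str
    r1: Read
    r2: Read
    sample: str | None = None


@dataclass(frozen=True)
class SampleSpec:
    name: str
    fwd_barcode: str
    fwd_primer: str
    rev_barcode: str = ""
    rev_primer: str = ""
    dialect: str = "amplicon"  # or "polyaseq"


@dataclass
class SampleSheet:
    samples: list[SampleSpec] = field(default_factory=list)

    def __post_init__(self):
        keys = set()
        for s in self.samples:
            k = self.effective_keys(s)
            if k in keys:
                raise ValueError(f"duplicate demultiplexing key for sample {s.name}")
            keys.add(k)

    def effective_keys(self, s: SampleSpec) -> tuple[str, str]:
        fwd = make_demux_key(s.fwd_barcode, s.fwd_primer)
        rev = (
            make_demux_key(s.rev_barcode, s.rev_primer)
            if s.dialect == "amplicon"
            else ""
        )
        return fwd, rev


def make_demux_key(barcode: str, primer: str) -> str:
    """8-bp demultiplexing key: the barcode, padded to 8 bp with the first
    primer bases when shorter (barcodes longer than 8 bp are truncated)."""
    if len(barcode) < 1:
        raise ValueError("barcode must be non-empty")
    if len(barcode) + len(primer) < DEMUX_KEY_LEN:
        raise ValueError("barcode + primer shorter than the 8 bp demux key")
    if len(barcode) >= DEMUX_KEY_LEN:
        return barcode[:DEMUX_KEY_LEN]
    return barcode + primer[: DEMUX_KEY_LEN - len(barcode)]


def demultiplex_pairs(
    pairs: list[ReadPair], sheet: SampleSheet
) -> tuple[dict[str, list[ReadPair]], list[ReadPair]]:
    """Assign read pairs to samples by exact 8-bp key match on both mates.

    Mates that match conflicting samples (or only one mate matches) are
    left unassigned.  Returns (per-sample reads, unassigned reads); the
    partition is exhaustive and disjoint.
    """
    key_map: dict[tuple[str, str], str] = {}
    for s in sheet.samples:
        if s.dialect == "amplicon":
            key_map[sheet.effective_keys(s)] = s.name
    assigned: dict[str, list[ReadPair]] = {s.name: [] for s in sheet.samples}
    unassigned: list[ReadPair] = []
    for pair in pairs:
        k = (pair.r1.seq[:DEMUX_KEY_LEN], pair.r2.seq[:DEMUX_KEY_LEN])
        name = key_map.get(k)
        if name is None:
            unassigned.append(pair)
        else:
            pair.sample = name
            assigned[name].append(pair)
    return assigned, unassigned


def demultiplex_reads(
    reads: list[Read], sheet: SampleSheet
) -> tuple[dict[str, list[Read]], list[Read]]:
    """Single-end (PolyA-seq) demultiplexing by the forward key only."""
    key_map = {
        sheet.effective_keys(s)[0]: s.name
        for s in sheet.samples
        if s.dialect == "polyaseq"
    }
    assigned: dict[str, list[Read]] = {s.name: [] for s in sheet.samples}
    unassigned: list[Read] = []
    for read in reads:
        name = key_map.get(read.seq[:DEMUX_KEY_LEN])
        if name is None:
            unassigned.append(read)
        else:
            read.sample = name
            assigned[name].append(read)
    return assigned, unassigned


def expected_downstream(target_ref: str, primer: str, n: int = 10) -> str:
    """The n reference bases immediately 3' of the primer on the target."""
    pos = target_ref.find(primer)
    if pos < 0:
        raise ValueError("primer not found in target reference")
    return target_ref[pos + len(primer) : pos + len(primer) + n]


def filter_amplicon_by_primer(
    pairs: list[ReadPair],
    fwd_primer: str,
    fwd_downstream: str,
    rev_primer: str,
    rev_downstream: str,
) -> tuple[list[ReadPair], list[ReadPair]]:
    """Keep pairs where each mate contains its primer immediately followed
    by the expected 10 reference bases (exact match)."""
    kept, dropped = [], []
    sig1 = fwd_primer + fwd_downstream
    sig2 = rev_primer + rev_downstream
    for pair in pairs:
        if sig1 in pair.r1.seq and sig2 in pair.r2.seq:
            kept.append(pair)
        else:
            dropped.append(pair)
    return kept, dropped


def filter_polyaseq_by_primer(
    reads: list[Read], primer: str
) -> tuple[list[Read], list[Read]]:
    """PolyA-seq primer filter and mask.

    A read survives iff it contains the nested primer with 7 A's imposed
    directly on it plus at least 8 further A's (i.e. >= 15 consecutive A's
    after the primer).  In survivors the prefix through the primer
    (barcode + primer) is masked to N; length and qualities are preserved.
    """
    needle = primer + "A" * (POLYA_PRIMER_IMPOSED + POLYA_ADDITIONAL)
    kept, dropped = [], []
    for read in reads:
        idx = read.seq.find(needle)
        if idx < 0:
            dropped.append(read)
            continue
        mask_end = idx + len(primer)
        masked = replace(
            read, seq="N" * mask_end + read.seq[mask_end:], qual=list(read.qual)
        )
        kept.append(masked)
    return kept, dropped


def trim_insert_portion(seq: str, target_ref: str, primer: str) -> str:
    """Insert portion of one mate: everything 3' of the maximal exact
    extension along the target reference starting from the primer.

    The mate is given as sequenced; ``target_ref`` must be oriented so the
    primer occurs on its forward strand (reverse mates are handled by the
    caller passing the reverse-complemented locus).  Returns "" when the
    read matches the reference along its full length (no insertion).
    """
    p = seq.find(primer)
    if p < 0:
        return ""
    ref_pos = target_ref.find(primer)
    if ref_pos < 0:
        raise ValueError("primer not found in target reference")
    i = p + len(primer)
    j = ref_pos + len(primer)
    while i < len(seq) and j < len(target_ref) and seq[i] == target_ref[j]:
        i += 1
        j += 1
    return seq[i:]


def collapse_pcr_duplicates(inserts: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Drop exact duplicate insert sequences (PCR repeats), keeping the
    first occurrence.  Input/output: (read_id, insert_seq) tuples."""
    seen: set[str] = set()
    out = []
    for read_id, ins in inserts:
        if ins in seen:
            continue
        seen.add(ins)
        out.append((read_id, ins))
    return out


def drop_short_inserts(
    inserts: list[tuple[str, str]], min_len: int = MIN_INSERT_LEN
) -> list[tuple[str, str]]:
    """Eliminate inserts shorter than 30 bp."""
    return [(rid, ins) for rid, ins in inserts if len(ins) >= min_len]
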