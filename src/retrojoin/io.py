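"""File I/O: FASTA/FASTQ (Phred+33), truth tables, reports, manifests.

All emitted text formats are fixed dialects so runs are byte-reproducible:
TSV with a header line (comments prefixed '#'), 6-column BED, Sanger
FASTQ.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .readprep import Read, ReadPair
from .simulate import TruthRecord


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: list[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            rec = SeqRecord(Seq(r.seq), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = list(r.qual)
            SeqIO.write([rec], fh, "fastq")


def read_fastq(path: str | Path) -> list[Read]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(Read(rec.id, str(rec.seq), list(rec.letter_annotations["phred_quality"])))
    return out


def write_paired_fastq(pairs: list[ReadPair], r1_path: str | Path, r2_path: str | Path) -> None:
    write_fastq([p.r1 for p in pairs], r1_path)
    write_fastq([p.r2 for p in pairs], r2_path)


def read_paired_fastq(r1_path: str | Path, r2_path: str | Path) -> list[ReadPair]:
    r1s = read_fastq(r1_path)
    r2s = read_fastq(r2_path)
    if len(r1s) != len(r2s):
        raise ValueError("mate files differ in record count")
    pairs = []
    for a, b in zip(r1s, r2s):
        rid = a.read_id.rsplit("/", 1)[0]
        pairs.append(ReadPair(rid, a, b))
    return pairs


_TRUTH_COLUMNS = [f.name for f in dataclasses.fields(TruthRecord)]


def write_truth_table(truths: list[TruthRecord], path: str | Path) -> None:
    rows = []
    for t in truths:
        d = dataclasses.asdict(t)
        d["true_insert_interval"] = f"{t.true_insert_interval[0]}-{t.true_insert_interval[1]}"
        rows.append(d)
    df = pd.DataFrame(rows, columns=_TRUTH_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> list[TruthRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.to_dict("records"):
        lo, hi = str(row["true_insert_interval"]).split("-")
        row["true_insert_interval"] = (int(lo), int(hi))
        for key in ("true_spliced", "true_en_dependent", "true_nqs_callable"):
            row[key] = str(row[key]) in ("True", "true", "1")
        out.append(TruthRecord(**row))
    return out


def write_tsv(df: pd.DataFrame, path: str | Path, comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """6-column BED: chrom, start, end, name, score, strand."""
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def write_manifest(params: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
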