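"""Seeded simulator for insertion events and reads in both assay dialects.

The generator emulates the statistical structure of the study libraries:

* **Amplicon dialect** — paired 250-nt reads over a CRISPR target locus.
  Each event inserts a fragment (reporter cassette with 3'-anchored 5'
  truncation, spliced or unspliced; plasmid; pegRNA scaffold; genomic flank
  within +/-5 kb of the cut; L1Hs) between two resected break ends, joined
  either directly, through a planted microhomology (0-10 bp), or through an
  "other sources" linker gap.
* **PolyA-seq dialect** — single reads of barcode + nested primer + poly(A)
  run (15-75 nt) + downstream genomic flank.  Endonuclease-dependent events
  sit at planted TTAAAAA nick sites genome-wide; EN-independent events fall
  uniformly within the DSB window.
* **Editing dialect** — reads over the locus with a planted substitution
  and per-position Phred control, so NQS callability is part of the truth.

Microhomology is planted by searching the source reference for a position
whose flanking bases reproduce the break-end sequence; the truth table
never trusts the plant — every junction's (mh, gap) is re-measured on the
finished construct by direct string extension, exactly mirroring the
coordinate-overlap definition the analysis uses.  Ground truth is therefore
exact even when a draw was not achievable and a smaller microhomology was
planted instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import revcomp
from .readprep import Read, ReadPair
from .refs import ReferenceSet

L1_REPORTER = "L1_REPORTER"
L1HS = "L1HS"
PLASMID_LENTI = "PLASMID_LENTI"
PLASMID_EDITOR = "PLASMID_EDITOR"
PEGRNA = "PEGRNA"
GENOMIC = "GENOMIC"
UNCLASSIFIED = "UNCLASSIFIED"

SOURCES = (L1_REPORTER, L1HS, PLASMID_LENTI, PLASMID_EDITOR, PEGRNA, GENOMIC)

_BASES = "ACGT"
_EXT_CTX = 30  # source context kept for truth extension measurement


def uniform_dist(lo: int, hi: int) -> dict[int, float]:
    """Uniform categorical distribution over the closed integer range."""
    n = hi - lo + 1
    return {k: 1.0 / n for k in range(lo, hi + 1)}


def point_mass(k: int) -> dict[int, float]:
    return {k: 1.0}


def default_mh_distribution() -> dict[int, float]:
    # direct joints plus short microhomologies with a decreasing trend
    return {0: 0.30, 1: 0.25, 2: 0.17, 3: 0.11, 4: 0.08, 5: 0.05, 6: 0.04}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_reads: int = 1000
    source_mixture: dict[str, float] = field(
        default_factory=lambda: {L1_REPORTER: 0.5, PLASMID_LENTI: 0.25, GENOMIC: 0.25}
    )
    splice_fraction: float = 0.5
    truncation_model: str = "uniform"
    mh_distribution: dict[int, float] = field(default_factory=default_mh_distribution)
    gap_fraction: float = 0.1
    gap_len_range: tuple[int, int] = (5, 30)
    polya_distribution: dict[int, float] = field(default_factory=lambda: uniform_dist(15, 75))
    en_dependent_fraction: float = 0.5
    dsb_window: int = 5000
    error_rate: float = 0.001
    quality_mean: float = 36.0
    quality_sd: float = 3.0
    quality_clamp: tuple[int, int] = (2, 40)
    read_len: int = 250
    insert_len_range: tuple[int, int] = (150, 400)
    min_reporter_frag: int = 150
    resection_max: int = 8

    def __post_init__(self):
        total = sum(self.source_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"source_mixture sums to {total}, expected 1")
        for label in self.source_mixture:
            if label not in SOURCES:
                raise ValueError(f"unknown source label {label!r}")
        for p in (
            self.splice_fraction,
            self.gap_fraction,
            self.en_dependent_fraction,
            self.error_rate,
            *self.source_mixture.values(),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for dist in (self.mh_distribution, self.polya_distribution):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError("distributions must sum to 1")


@dataclass
class TruthRecord:
    read_id: str
    true_source: str = UNCLASSIFIED
    true_orientation: str = "+"
    true_insert_ref: str = ""
    true_insert_interval: tuple[int, int] = (0, 0)
    true_mh_left: int = 0
    true_gap_left: int = 0
    true_mh_right: int = 0
    true_gap_right: int = 0
    true_polya_len: int = 0
    true_edit: str = "unedited"
    true_nqs_callable: bool = False
    true_junction_pos: int = -1
    true_junction_call: int = -1  # measurable junction under alignment scoring
    true_junction_right: int = -1
    true_chrom: str = ""
    true_strand: str = "+"
    true_spliced: bool = False
    true_en_dependent: bool = False

    @property
    def true_gap_len(self) -> int:
        return max(self.true_gap_left, self.true_gap_right)

    def check_invariants(self) -> None:
        if self.true_mh_left and self.true_gap_left:
            raise AssertionError("left junction has both microhomology and gap")
        if self.true_mh_right and self.true_gap_right:
            raise AssertionError("right junction has both microhomology and gap")


@dataclass
class InsertionEvent:
    edited_locus: str
    truth: TruthRecord
    locus_start: int  # genomic coordinate of edited_locus[0]
    j_left: int  # locus-local left break end
    j_right: int  # locus-local right break end
    fragment: str
    filler: str = ""

    @property
    def insert_seq(self) -> str:
        return self.filler + self.fragment


# --------------------------------------------------------------------------
# low-level draws and truth measurement


def _draw_categorical(rng: np.random.Generator, dist: dict) -> int | str:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _common_prefix(a: str, b: str) -> int:
    k = 0
    n = min(len(a), len(b))
    while k < n and a[k] == b[k]:
        k += 1
    return k


def _measure_left(locus: str, j_left: int, filler: str, fragment: str, preceding: str):
    """(mh, gap) at the left junction by direct string extension: the
    target alignment end extends from j_left while the inserted bases match
    the reference continuation; the insert alignment start extends backwards
    while read bases match the source bases preceding the fragment."""
    combined = filler + fragment
    e = _common_prefix(combined, locus[j_left:])
    t_end = j_left + e
    before = locus[:j_left] + filler
    k = 0
    while k < len(preceding) and k < len(before) and before[-1 - k] == preceding[-1 - k]:
        k += 1
    i_start = j_left + len(filler) - k
    if i_start <= t_end:
        return t_end - i_start, 0
    return 0, i_start - t_end


def _measure_right(locus: str, j_right: int, filler: str, fragment: str, following: str):
    """(mh, gap) at the right junction, mirrored."""
    combined = filler + fragment
    a = 0
    while a < len(combined) and a < j_right and combined[-1 - a] == locus[j_right - 1 - a]:
        a += 1
    f = _common_prefix(following, locus[j_right:])
    return a + f, 0


# --------------------------------------------------------------------------
# fragment planting


def _plant_start_plus(rng, source: str, needle: str, lo: int, hi: int, nxt: str, prev: str):
    """Position s0 in [lo, hi] with source[s0-m:s0] == needle, source[s0] !=
    nxt and source[s0-m-1] != prev (extension stops exactly at m)."""
    m = len(needle)
    if hi < lo:
        return None
    if m == 0:
        for _ in range(600):
            s0 = int(rng.integers(lo, hi + 1))
            if s0 < len(source) and source[s0] == nxt:
                continue
            if s0 - 1 >= 0 and prev and source[s0 - 1] == prev:
                continue
            return s0
        return None
    cands = []
    start = 0
    while len(cands) < 4000:
        p = source.find(needle, start)
        if p < 0:
            break
        s0 = p + m
        if lo <= s0 <= hi:
            ok = not (s0 < len(source) and source[s0] == nxt)
            if ok and s0 - m - 1 >= 0 and prev:
                ok = source[s0 - m - 1] != prev
            if ok:
                cands.append(s0)
        start = p + 1
    if not cands:
        return None
    return cands[int(rng.integers(0, len(cands)))]


def _choose_fragment(rng, refset: ReferenceSet, cfg: SimulationConfig, source: str,
                     orientation: str, locus: str, j_left: int, j_right: int,
                     mh_target: int, spliced: bool):
    """Select a source interval that plants ``mh_target`` at the event's
    adjustable junction.  Returns (fragment, ref_name, interval, preceding,
    following, achieved_spliced) or None when no placement exists (caller
    retries with a smaller target)."""
    g = refset.genome[refset.target_chrom]
    ctx = _EXT_CTX

    if source == L1_REPORTER:
        cassette = refset.spliced_reporter() if spliced else refset.reporter
        i0, i1 = refset.intron
        lo, hi = 1, len(cassette) - cfg.min_reporter_frag
        if orientation == "+":
            # left junction adjustable through the truncation point
            needle = locus[j_left - mh_target : j_left]
            t = _plant_start_plus(rng, cassette, needle, lo, hi,
                                  nxt=locus[j_left], prev=locus[j_left - mh_target - 1])
            if t is None:
                return None
            frag = cassette[t:]
            preceding = cassette[max(0, t - ctx) : t]
            following = ""
        else:
            # right junction adjustable; fragment is the reverse complement
            # of the 3'-anchored cassette suffix
            needle = revcomp(locus[j_right : j_right + mh_target])
            t = _plant_start_plus(
                rng, cassette, needle, lo, hi,
                nxt=revcomp(locus[j_right - 1]),
                prev=revcomp(locus[j_right + mh_target]),
            )
            if t is None:
                return None
            frag = revcomp(cassette[t:])
            preceding = ""
            following = revcomp(cassette[max(0, t - ctx) : t])
        t_uns = t if (not spliced or t < i0) else t + (i1 - i0)
        interval = (t_uns, len(refset.reporter))
        return frag, "reporter", interval, preceding, following, spliced

    # --- free-interval sources ---------------------------------------------
    if source == GENOMIC:
        cut = refset.cut_site
        w = cfg.dsb_window
        foot_lo, foot_hi = refset.target_locus[0] - 400, refset.target_locus[1] + 400
        windows = [(max(0, cut - w), foot_lo), (foot_hi, min(len(g), cut + w))]
        side = int(rng.integers(0, 2))
        win_lo, win_hi = windows[side]
        seq, name, off = g[win_lo:win_hi], refset.target_chrom, win_lo
    elif source == PLASMID_LENTI:
        seq, name, off = refset.plasmid_lenti, "plasmid_lenti", 0
    elif source == PLASMID_EDITOR:
        seq, name, off = refset.plasmid_editor, "plasmid_editor", 0
    elif source == PEGRNA:
        seq, name, off = refset.pegrna_scaffold, "pegrna_scaffold", 0
    elif source == L1HS:
        seq, name, off = refset.l1hs, "l1hs", 0
    else:
        raise ValueError(f"unknown source {source!r}")

    if source == PEGRNA:
        frag_len = int(rng.integers(30, len(seq) - 10))
    else:
        frag_len = int(rng.integers(cfg.insert_len_range[0], cfg.insert_len_range[1] + 1))
    if frag_len > len(seq) - 2:
        return None

    if orientation == "+":
        needle = locus[j_left - mh_target : j_left]
        s0 = _plant_start_plus(rng, seq, needle, max(1, mh_target), len(seq) - frag_len,
                               nxt=locus[j_left], prev=locus[j_left - mh_target - 1])
        if s0 is None:
            return None
        frag = seq[s0 : s0 + frag_len]
        preceding = seq[max(0, s0 - ctx) : s0]
        following = seq[s0 + frag_len : s0 + frag_len + ctx]
        interval = (off + s0, off + s0 + frag_len)
    else:
        # fragment = revcomp(seq[e0-frag_len : e0]); the bases "preceding"
        # the fragment start are the complements of seq[e0:], so the needle
        # is searched as its reverse complement ending at e0
        needle = revcomp(locus[j_left - mh_target : j_left])
        # _plant_start_plus finds s with seq[s-m:s]==needle; we need
        # seq[e0:e0+m]==needle, i.e. occurrence start e0 = s - m
        m = mh_target
        s = _plant_start_plus(rng, seq, needle, max(frag_len + m, m),
                              len(seq) - 1, nxt=revcomp(locus[j_left - m - 1]),
                              prev=revcomp(locus[j_left]))
        if s is None:
            return None
        e0 = s - m
        frag = revcomp(seq[e0 - frag_len : e0])
        preceding = revcomp(seq[e0 : e0 + ctx])
        following = revcomp(seq[max(0, e0 - frag_len - ctx) : e0 - frag_len])
        interval = (off + e0 - frag_len, off + e0)
    return frag, name, interval, preceding, following, False


# --------------------------------------------------------------------------
# public simulation entry points


def locus_window(refset: ReferenceSet, half: int = 600) -> tuple[int, str]:
    """Genomic window the amplicon events are constructed in; returns
    (window start, window sequence)."""
    g = refset.genome[refset.target_chrom]
    lo = refset.cut_site - half
    return lo, g[lo : refset.cut_site + half]


def simulate_insertion_events(refset: ReferenceSet, cfg: SimulationConfig) -> list[InsertionEvent]:
    """Generate ``cfg.n_reads`` insertion events at the CRISPR cut site.

    Each event records ground truth for source, orientation, interval,
    junction microhomology/gap on both sides, and junction positions.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    lo, locus = locus_window(refset)
    cut_local = refset.cut_site - lo
    events: list[InsertionEvent] = []
    for i in range(cfg.n_reads):
        source = _draw_categorical(rng, cfg.source_mixture)
        orientation = "+" if rng.random() < 0.5 else "-"
        d_left = int(rng.integers(0, cfg.resection_max + 1))
        d_right = int(rng.integers(0, cfg.resection_max + 1))
        j_left = cut_local - d_left
        j_right = cut_local + d_right
        spliced = source == L1_REPORTER and rng.random() < cfg.splice_fraction
        use_gap = rng.random() < cfg.gap_fraction
        mh_draw = 0 if use_gap else int(_draw_categorical(rng, cfg.mh_distribution))

        placed = None
        for m in range(mh_draw, -1, -1):
            placed = _choose_fragment(rng, refset, cfg, source, orientation,
                                      locus, j_left, j_right, m, spliced)
            if placed is not None:
                break
        if placed is None:
            raise RuntimeError(f"could not place fragment for source {source}")
        frag, ref_name, interval, preceding, following, spliced = placed

        filler = ""
        if use_gap:
            gap_len = int(rng.integers(cfg.gap_len_range[0], cfg.gap_len_range[1] + 1))
            for _ in range(100):
                filler = _random_dna(rng, gap_len)
                if filler[0] == locus[j_left]:
                    continue
                if preceding and filler[-1] == preceding[-1]:
                    continue
                break

        mh_l, gap_l = _measure_left(locus, j_left, filler, frag, preceding)
        mh_r, gap_r = _measure_right(locus, j_right, filler, frag, following)
        edited = locus[:j_left] + filler + frag + locus[j_right:]
        truth = TruthRecord(
            read_id=f"ampl{i:06d}",
            true_source=source,
            true_orientation=orientation,
            true_insert_ref=ref_name,
            true_insert_interval=interval,
            true_mh_left=mh_l,
            true_gap_left=gap_l,
            true_mh_right=mh_r,
            true_gap_right=gap_r,
            true_junction_pos=lo + j_left,
            true_junction_right=lo + j_right,
            true_chrom=refset.target_chrom,
            true_spliced=spliced,
        )
        truth.check_invariants()
        events.append(InsertionEvent(edited, truth, lo, j_left, j_right, frag, filler))
    return events


@dataclass(frozen=True)
class AmpliconDesign:
    """Primer pair flanking the cut site inside the target locus."""

    fwd_primer: str
    rev_primer: str
    fwd_offset: int  # locus-window coordinate of the forward primer start
    rev_offset: int  # locus-window coordinate just past the reverse primer site


def default_amplicon_design(refset: ReferenceSet) -> AmpliconDesign:
    lo, locus = locus_window(refset)
    cut = refset.cut_site - lo
    return AmpliconDesign(
        fwd_primer=locus[cut - 120 : cut - 100],
        rev_primer=revcomp(locus[cut + 100 : cut + 120]),
        fwd_offset=cut - 120,
        rev_offset=cut + 120,
    )


def _finish_read(rng, cfg: SimulationConfig, seq: str) -> tuple[str, list[int]]:
    seq = seq[: cfg.read_len]
    out = list(seq)
    if cfg.error_rate > 0:
        hits = np.nonzero(rng.random(len(out)) < cfg.error_rate)[0]
        for idx in hits:
            choices = [b for b in _BASES if b != out[idx]]
            out[idx] = choices[int(rng.integers(0, 3))]
    qual = np.clip(
        np.rint(rng.normal(cfg.quality_mean, cfg.quality_sd, len(out))),
        cfg.quality_clamp[0],
        cfg.quality_clamp[1],
    ).astype(int)
    return "".join(out), qual.tolist()


def simulate_amplicon_reads(
    events: list[InsertionEvent],
    design: AmpliconDesign,
    fwd_barcode: str,
    rev_barcode: str,
    cfg: SimulationConfig,
) -> tuple[list[ReadPair], list[TruthRecord]]:
    """Paired amplicon reads over the edited loci.  R1 starts with the
    forward barcode + primer, R2 with the reverse barcode + primer."""
    rng = np.random.default_rng([cfg.seed, 2])
    pairs, truths = [], []
    for ev in events:
        edited = ev.edited_locus
        if design.fwd_primer not in edited[: ev.j_left]:
            raise ValueError("forward primer does not flank the cut site")
        shift = ev.j_left + len(ev.insert_seq) - ev.j_right
        rev_site_end = design.rev_offset + shift
        r1_core = edited[design.fwd_offset :]
        r2_core = revcomp(edited[:rev_site_end])
        r1_seq, r1_q = _finish_read(rng, cfg, (fwd_barcode + r1_core))
        r2_seq, r2_q = _finish_read(rng, cfg, (rev_barcode + r2_core))
        rid = ev.truth.read_id
        pairs.append(
            ReadPair(rid, Read(rid + "/1", r1_seq, r1_q), Read(rid + "/2", r2_seq, r2_q))
        )
        truths.append(ev.truth)
    return pairs, truths


def simulate_polyaseq_reads(
    refset: ReferenceSet,
    cfg: SimulationConfig,
    barcode: str,
    primer: str,
) -> tuple[list[Read], list[TruthRecord]]:
    """Single-end PolyA-seq reads: barcode + nested primer + poly(A) run +
    genomic flank downstream of the insertion point.

    EN-dependent events are placed at planted TTAAAAA nick sites; EN-
    independent events fall uniformly within ``dsb_window`` of the cut.
    The truth poly(A) length is the full junction homopolymer run (drawn
    tail plus any templated genomic A's), which is what any sequencing
    readout can measure.
    """
    if cfg.en_dependent_fraction > 0 and not refset.motif_sites:
        raise ValueError("no planted motif sites available for EN-dependent events")
    rng = np.random.default_rng([cfg.seed, 3])
    prefix = barcode + primer
    reads, truths = [], []
    for i in range(cfg.n_reads):
        en = rng.random() < cfg.en_dependent_fraction
        if en:
            site = refset.motif_sites[int(rng.integers(0, len(refset.motif_sites)))]
            chrom, pos, strand = site.chrom, site.nick_pos, site.strand
        else:
            chrom = refset.target_chrom
            g = refset.genome[chrom]
            pos = int(
                np.clip(
                    refset.cut_site + rng.integers(-cfg.dsb_window, cfg.dsb_window + 1),
                    200,
                    len(g) - 200,
                )
            )
            strand = "+" if rng.random() < 0.5 else "-"
        g = refset.genome[chrom]
        tail = int(_draw_categorical(rng, cfg.polya_distribution))
        flank_len = max(30, cfg.read_len - len(prefix) - tail)
        if strand == "+":
            flank = g[pos : pos + flank_len]
        else:
            flank = revcomp(g[max(0, pos - flank_len) : pos])
        intended = prefix + "A" * tail + flank
        polya_span = _measurable_polya_span("X" * len(prefix) + intended[len(prefix) :])
        shift = _junction_call_shift(g, pos, strand, tail)
        call = pos - shift if strand == "+" else pos + shift
        seq, qual = _finish_read(rng, cfg, intended)
        rid = f"pa{i:06d}"
        reads.append(Read(rid, seq, qual))
        truths.append(
            TruthRecord(
                read_id=rid,
                true_source=L1_REPORTER,
                true_polya_len=polya_span,
                true_junction_pos=pos,
                true_junction_call=call,
                true_chrom=chrom,
                true_strand=strand,
                true_en_dependent=en,
            )
        )
    return reads, truths


NEG = float("-inf")


def _measurable_polya_span(seq: str) -> int:
    """Read-span of the best local alignment against a long poly(A)
    reference under match +1 / mismatch -2 / gap 2+L: what the
    alignment-based measurement reports for an error-free read.  Non-A
    read bases can be mismatched (-2 each) or skipped by a query gap
    (2 + L), both of which stay inside the reported span.  Ties resolve to
    the shortest/earliest segment, matching the aligner."""
    best, best_span = 0.0, 0
    m_score, m_start = 0.0, 0  # state: last read base aligned (match/mismatch)
    g_score, g_start = NEG, 0  # state: last read base inside a query gap
    for i, ch in enumerate(seq):
        v = 1.0 if ch == "A" else -2.0
        if m_score >= g_score:
            prev, prev_start = m_score, m_start
        else:
            prev, prev_start = g_score, g_start
        if prev > 0:
            nm, ns = prev + v, prev_start
        else:
            nm, ns = v, i
        ng, ngs = (m_score - 3.0, m_start) if m_score - 3.0 >= g_score - 1.0 else (g_score - 1.0, g_start)
        m_score, m_start = nm, ns
        g_score, g_start = ng, ngs
        if m_score > best:
            best, best_span = m_score, i - m_start + 1
    return best_span


def _junction_call_shift(g: str, pos: int, strand: str, max_ext: int) -> int:
    """How far the genomic alignment's 5' edge extends into the poly(A)
    tail through templated genomic A's (T's on the minus strand), under
    match +1 / mismatch -2 / gap 2+L (a gap may skip non-matching genomic
    bases to reach a farther run); ties keep the shorter extension."""
    target = "A" if strand == "+" else "T"
    m_score, g_score = 0.0, NEG
    best_s, best_k = 0.0, 0
    for k in range(1, max_ext + 1):
        idx = pos - k if strand == "+" else pos + k - 1
        if idx < 0 or idx >= len(g):
            break
        v = 1.0 if g[idx] == target else -2.0
        nm = max(m_score, g_score) + v
        ng = max(m_score - 3.0, g_score - 1.0)
        m_score, g_score = nm, ng
        if m_score > best_s:
            best_s, best_k = m_score, k
    return best_k


DEFAULT_FWD_BARCODE = "ACGTACGT"
DEFAULT_REV_BARCODE = "TGCATGCA"
# nested capture primer for the PolyA-seq dialect; a fixed 20-mer that is
# essentially never present in a random mini-genome
POLYA_NESTED_PRIMER = "GTTCAGACGTGCTCTTCCGA"
DEFAULT_POLYA_BARCODE = "CAGTTGCA"


def default_sample_sheet(refset: ReferenceSet, dialect: str = "amplicon"):
    """One-sample sheet matching the simulator's default barcodes/primers."""
    from .readprep import SampleSheet, SampleSpec

    if dialect == "amplicon":
        design = default_amplicon_design(refset)
        return SampleSheet(
            [
                SampleSpec(
                    name="S1",
                    fwd_barcode=DEFAULT_FWD_BARCODE,
                    fwd_primer=design.fwd_primer,
                    rev_barcode=DEFAULT_REV_BARCODE,
                    rev_primer=design.rev_primer,
                    dialect="amplicon",
                )
            ]
        )
    if dialect == "polyaseq":
        return SampleSheet(
            [
                SampleSpec(
                    name="P1",
                    fwd_barcode=DEFAULT_POLYA_BARCODE,
                    fwd_primer=POLYA_NESTED_PRIMER,
                    dialect="polyaseq",
                )
            ]
        )
    raise ValueError(f"unknown dialect {dialect!r}")


@dataclass(frozen=True)
class JunctionCase:
    """One constructed junction with provably unambiguous ground truth.

    The target flank is drawn over {A,C} and the insert body (and any
    linker filler) over {G,T}; the only bases the two alphabets share are
    the planted microhomology, copied verbatim, and the insert reference
    begins/ends exactly at the junction-adjacent position.  No alignment —
    gapped or not — can therefore extend past the planted boundary, so the
    recovered (mh, gap) of a correct implementation equals the planted
    values exactly.
    """

    read_seq: str  # the mate as sequenced (right-side cases are revcomp)
    target_ref: str
    insert_ref: str
    side: str
    orientation: str
    mh: int
    gap: int
    cut_site_ref: int


def construct_junction_case(
    rng: np.random.Generator,
    side: str,
    orientation: str,
    mh: int = 0,
    gap: int = 0,
    flank_len: int = 80,
    insert_len: int = 60,
    target_extra: int = 40,
) -> JunctionCase:
    """Build a junction read with planted microhomology or linker gap."""
    if mh and gap:
        raise ValueError("a junction has either microhomology or a gap, not both")

    def draw(alphabet: str, n: int) -> str:
        return "".join(alphabet[i] for i in rng.integers(0, 2, size=n))

    body = draw("GT", insert_len)
    filler = draw("GT", gap)
    if side == "left":
        target_ref = draw("AC", flank_len + target_extra)
        j = flank_len
        core = target_ref[j - mh : j] + body
        read_locus = target_ref[:j] + filler + body
    else:
        target_ref = draw("AC", target_extra + flank_len)
        j = target_extra
        core = body + target_ref[j : j + mh]
        read_locus = body + filler + target_ref[j:]
    insert_ref = core if orientation == "+" else revcomp(core)
    read_seq = read_locus if side == "left" else revcomp(read_locus)
    return JunctionCase(
        read_seq=read_seq,
        target_ref=target_ref,
        insert_ref=insert_ref,
        side=side,
        orientation=orientation,
        mh=mh,
        gap=gap,
        cut_site_ref=j,
    )


@dataclass(frozen=True)
class EditSpec:
    """A programmed point edit at a genomic position."""

    position: int
    alt_base: str


def simulate_edited_reads(
    refset: ReferenceSet,
    edit_spec: EditSpec,
    cfg: SimulationConfig,
    edited_fraction: float = 0.37,
    site_quality: int = 36,
    flank_quality: int | None = None,
) -> tuple[list[Read], list[TruthRecord], str]:
    """Reads over the target locus with a planted substitution.

    Exactly ``round(edited_fraction * n_reads)`` reads carry the edit, in a
    seeded random order.  ``site_quality`` (and optionally ``flank_quality``
    for the five bases on either side) override the quality model at the
    edited position so NQS pass/fail is plantable.  Returns (reads, truths,
    target reference window).
    """
    g = refset.genome[refset.target_chrom]
    ref_lo = refset.cut_site - 125
    target_ref = g[ref_lo : ref_lo + 250]
    t_local = edit_spec.position - ref_lo
    if not 0 <= t_local < len(target_ref):
        raise ValueError("edit position outside the target locus window")
    rng = np.random.default_rng([cfg.seed, 4])
    n = cfg.n_reads
    n_edited = int(round(edited_fraction * n))
    edited_flags = np.zeros(n, dtype=bool)
    edited_flags[rng.permutation(n)[:n_edited]] = True
    reads, truths = [], []
    for i in range(n):
        base_seq = target_ref
        if edited_flags[i]:
            base_seq = target_ref[:t_local] + edit_spec.alt_base + target_ref[t_local + 1 :]
        seq, qual = _finish_read(rng, cfg, base_seq)
        nqs_ok = False
        if edited_flags[i]:
            qual[t_local] = site_quality
            flanks = list(range(max(0, t_local - 5), t_local)) + list(
                range(t_local + 1, min(len(qual), t_local + 6))
            )
            if flank_quality is not None:
                for p in flanks:
                    qual[p] = flank_quality
            nqs_ok = site_quality >= 30 and all(qual[p] >= 20 for p in flanks)
        rid = f"edit{i:06d}"
        reads.append(Read(rid, seq, qual))
        truths.append(
            TruthRecord(
                read_id=rid,
                true_edit="edited" if edited_flags[i] else "unedited",
                true_nqs_callable=bool(nqs_ok),
                true_junction_pos=edit_spec.position,
                true_chrom=refset.target_chrom,
            )
        )
    return reads, truths, target_ref
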