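"""Synthetic reference universe: mini-genome, L1 reporter cassette, plasmids.

The generator builds a desk-scale stand-in for the references the assays
align against: a two-chromosome random genome carrying one CRISPR target
locus (protospacer + NGG PAM, cut site 3 bp 5' of the PAM), planted
endonuclease consensus motif sites (5'-TTAAAAA-3' nick sites on both
strands), and one duplicated segment for mapping-ambiguity tests; a
reporter cassette (ORF1/ORF2, 3'UTR with an antisense GFP interrupted by a
900-bp intron, SV40 polyA); lentiviral and editor plasmids; a pegRNA
scaffold; and an L1Hs consensus stand-in.  Sequence elements shared between
references (vector backbone piece, L1Hs-homologous piece, genomic
duplication) are recorded explicitly in ``shared_intervals`` so the
source-attribution rules can be applied declaratively.

All coordinates are 0-based half-open; the cut site and motif nick
positions are between-base offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import revcomp

BASES = np.array(list("ACGT"))

# motif planted on the forward strand of a plus-strand nick site: the EN
# nick falls between TT and AAAAA, i.e. 2 bases into the planted 7-mer
MOTIF_PLUS = "TTAAAAA"
MOTIF_MINUS = revcomp(MOTIF_PLUS)  # "TTTTTAA"; nick 5 bases into the 7-mer
NICK_OFFSET_PLUS = 2
NICK_OFFSET_MINUS = 5


@dataclass(frozen=True)
class RefParams:
    """Size settings for :func:`build_reference_set`."""

    chrom_lengths: tuple[tuple[str, int], ...] = (("chr1", 120_000), ("chr2", 100_000))
    reporter_len: int = 7_000
    plasmid_lenti_len: int = 8_000
    plasmid_editor_len: int = 6_000
    pegrna_scaffold_len: int = 90
    l1hs_len: int = 6_000
    n_motif_sites: int = 600
    dup_segment_len: int = 1_000
    shared_segment_len: int = 150


@dataclass(frozen=True)
class SharedInterval:
    ref_a: str
    interval_a: tuple[int, int]
    ref_b: str
    interval_b: tuple[int, int]


@dataclass(frozen=True)
class MotifSite:
    chrom: str
    nick_pos: int  # between-base coordinate of the EN nick
    strand: str  # motif strand: '+' reads TTAAAAA on the forward strand


@dataclass
class ReferenceSet:
    genome: dict[str, str]
    target_chrom: str
    target_locus: tuple[int, int]
    cut_site: int  # between-base genomic coordinate, 3 bp 5' of the PAM
    protospacer: tuple[int, int]
    pam: tuple[int, int]
    reporter: str
    reporter_features: dict[str, tuple[int, int]]
    plasmid_lenti: str
    plasmid_editor: str
    pegrna_scaffold: str
    pegrna_interval: tuple[int, int]  # scaffold location on plasmid_editor
    l1hs: str
    shared_intervals: list[SharedInterval]
    motif_sites: list[MotifSite]
    intron_assay_primers: tuple[str, str] = ("", "")
    params: RefParams = field(default_factory=RefParams)

    @property
    def intron(self) -> tuple[int, int]:
        return self.reporter_features["intron"]

    def spliced_reporter(self) -> str:
        i0, i1 = self.intron
        return self.reporter[:i0] + self.reporter[i1:]

    def reference_sequences(self) -> dict[str, str]:
        """All alignment references keyed by name (genome per chromosome)."""
        out = dict(self.genome)
        out["reporter"] = self.reporter
        out["plasmid_lenti"] = self.plasmid_lenti
        out["plasmid_editor"] = self.plasmid_editor
        out["l1hs"] = self.l1hs
        return out

    def shared_for(self, ref_a: str, ref_b: str) -> list[SharedInterval]:
        out = []
        for si in self.shared_intervals:
            if (si.ref_a, si.ref_b) == (ref_a, ref_b):
                out.append(si)
            elif (si.ref_b, si.ref_a) == (ref_a, ref_b):
                out.append(
                    SharedInterval(si.ref_b, si.interval_b, si.ref_a, si.interval_a)
                )
        return out


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def build_reference_set(seed: int, params: RefParams = RefParams()) -> ReferenceSet:
    """Deterministically generate the full reference universe for ``seed``.

    Raises ``ValueError`` when the requested sizes cannot host all planted
    features (genome < 200 kb over two chromosomes, reporter < 6 kb, or a
    motif-site count that does not fit the genome at the enforced spacing).
    """
    chrom_lengths = dict(params.chrom_lengths)
    if len(chrom_lengths) < 2 or sum(chrom_lengths.values()) < 200_000:
        raise ValueError("genome must span >= 200 kb across >= 2 chromosomes")
    if params.reporter_len < 6_000:
        raise ValueError("reporter must be >= 6 kb to host all cassette features")

    rng = np.random.default_rng(seed)
    genome = {c: list(_random_dna(rng, n)) for c, n in chrom_lengths.items()}
    chroms = list(genome)

    # --- CRISPR target locus on the first chromosome -----------------------
    target_chrom = chroms[0]
    tlen = chrom_lengths[target_chrom]
    proto_start = tlen // 2
    protospacer = (proto_start, proto_start + 20)
    pam = (proto_start + 20, proto_start + 23)
    # NGG PAM; protospacer stays random
    genome[target_chrom][pam[0] + 1] = "G"
    genome[target_chrom][pam[0] + 2] = "G"
    cut_site = pam[0] - 3
    target_locus = (cut_site - 200, cut_site + 200)

    # --- duplicated genomic segment (mapping ambiguity), far from the locus
    dup_len = params.dup_segment_len
    dup_a = (10_000, 10_000 + dup_len)
    other_chrom = chroms[1]
    dup_b = (20_000, 20_000 + dup_len)
    seg = genome[target_chrom][dup_a[0] : dup_a[1]]
    genome[other_chrom][dup_b[0] : dup_b[1]] = seg

    # --- planted EN consensus motif sites ----------------------------------
    blocked: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    blocked[target_chrom].append((target_locus[0] - 800, target_locus[1] + 800))
    blocked[target_chrom].append((dup_a[0] - 50, dup_a[1] + 50))
    blocked[other_chrom].append((dup_b[0] - 50, dup_b[1] + 50))

    motif_sites: list[MotifSite] = []
    total_len = sum(chrom_lengths.values())
    max_tries = params.n_motif_sites * 200
    tries = 0
    while len(motif_sites) < params.n_motif_sites:
        tries += 1
        if tries > max_tries:
            raise ValueError("genome too small to plant the requested motif sites")
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        clen = chrom_lengths[chrom]
        x = int(rng.integers(100, clen - 100))
        if any(lo - 20 <= x <= hi + 20 for lo, hi in blocked[chrom]):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        motif = MOTIF_PLUS if strand == "+" else MOTIF_MINUS
        # planted sites are unambiguous truth anchors: reject contexts where
        # a nearby homopolymer run could let a poly(A)-primed alignment jump
        # the nick (gapped extension into the run)
        if strand == "+":
            context = "".join(genome[chrom][max(0, x - 30) : x])
            if "AAAA" in context:
                continue
        else:
            context = "".join(genome[chrom][x + 7 : x + 37])
            if "TTTT" in context:
                continue
        genome[chrom][x : x + 7] = list(motif)
        nick = x + (NICK_OFFSET_PLUS if strand == "+" else NICK_OFFSET_MINUS)
        motif_sites.append(MotifSite(chrom, nick, strand))
        blocked[chrom].append((x - 10, x + 17))
    motif_sites.sort(key=lambda m: (m.chrom, m.nick_pos))
    del total_len

    genome_str = {c: "".join(s) for c, s in genome.items()}

    # --- reporter cassette --------------------------------------------------
    rlen = params.reporter_len
    reporter = list(_random_dna(rng, rlen))
    slen = params.shared_segment_len
    features = {
        "orf1": (500, 1_500),
        "orf2": (1_550, 5_000),
        "utr3": (5_050, rlen - 100),
        "gfp_antisense": (5_100, 6_500),
        "intron": (5_300, 6_200),
        "sv40_polya": (rlen - 100, rlen),
    }
    if features["intron"][1] >= features["gfp_antisense"][1]:
        raise ValueError("reporter too small: intron must sit inside antisense GFP")
    # canonical GT..AG splice boundaries on the cassette (antisense gene, but
    # the simulator removes the annotated interval exactly; boundary bases
    # are cosmetic)
    i0, i1 = features["intron"]
    reporter[i0 : i0 + 2] = ["G", "T"]
    reporter[i1 - 2 : i1] = ["A", "G"]

    # --- plasmids, pegRNA scaffold, L1Hs stand-in ---------------------------
    plasmid_lenti = list(_random_dna(rng, params.plasmid_lenti_len))
    plasmid_editor = list(_random_dna(rng, params.plasmid_editor_len))
    pegrna_scaffold = _random_dna(rng, params.pegrna_scaffold_len)
    l1hs = list(_random_dna(rng, params.l1hs_len))

    # vector element shared by the reporter construct and the lenti plasmid,
    # placed at the reporter 5' end (outside the cassette ORFs)
    lenti_shared_on_lenti = (2_000, 2_000 + slen)
    plasmid_lenti[2_000 : 2_000 + slen] = reporter[0:slen]
    # L1Hs-homologous element (non-codon-optimized remnant) next to it
    l1hs_shared_on_l1hs = (3_000, 3_000 + slen)
    l1hs[3_000 : 3_000 + slen] = reporter[slen : 2 * slen]
    # pegRNA scaffold embedded in the editor plasmid
    peg_iv = (1_000, 1_000 + params.pegrna_scaffold_len)
    plasmid_editor[peg_iv[0] : peg_iv[1]] = list(pegrna_scaffold)

    reporter_str = "".join(reporter)
    shared = [
        SharedInterval("reporter", (0, slen), "plasmid_lenti", lenti_shared_on_lenti),
        SharedInterval("reporter", (slen, 2 * slen), "l1hs", l1hs_shared_on_l1hs),
        SharedInterval(target_chrom, dup_a, other_chrom, dup_b),
        SharedInterval("plasmid_editor", peg_iv, "pegrna_scaffold", (0, params.pegrna_scaffold_len)),
    ]

    # intron-assay primer pair: spans 1192 bp on the unspliced cassette and
    # 292 bp once the 900-bp intron is removed (construct geometry mirrors
    # the published cassette)
    fwd_start = i0 - 146
    rev_end = i1 + 146
    fwd_primer = reporter_str[fwd_start : fwd_start + 20]
    rev_primer = revcomp(reporter_str[rev_end - 20 : rev_end])

    return ReferenceSet(
        genome=genome_str,
        target_chrom=target_chrom,
        target_locus=target_locus,
        cut_site=cut_site,
        protospacer=protospacer,
        pam=pam,
        reporter=reporter_str,
        reporter_features=features,
        plasmid_lenti="".join(plasmid_lenti),
        plasmid_editor="".join(plasmid_editor),
        pegrna_scaffold=pegrna_scaffold,
        pegrna_interval=peg_iv,
        l1hs="".join(l1hs),
        shared_intervals=shared,
        motif_sites=motif_sites,
        intron_assay_primers=(fwd_primer, rev_primer),
        params=params,
    )


def in_silico_pcr(template: str, fwd_primer: str, rev_primer: str) -> int | None:
    """Length of the PCR product the primer pair would amplify, or ``None``.

    The forward primer must occur on the forward strand and the reverse
    primer (as its reverse complement) downstream of it; the product spans
    from the forward primer 5' end to the reverse primer 5' end inclusive.
    """
    f = template.find(fwd_primer)
    if f < 0:
        return None
    rc = revcomp(rev_primer)
    r = template.find(rc, f + len(fwd_primer))
    if r < 0:
        return None
    return r + len(rc) - f


def intron_assay(refset: ReferenceSet) -> tuple[int | None, int | None]:
    """In-silico intron assay: PCR product lengths on the unspliced and
    spliced reporter; retrotransposition removes the intron at the DNA level
    and shortens the product by the intron length."""
    fwd, rev = refset.intron_assay_primers
    return (
        in_silico_pcr(refset.reporter, fwd, rev),
        in_silico_pcr(refset.spliced_reporter(), fwd, rev),
    )
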