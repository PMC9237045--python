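"""Affine local alignment primitives shared by every analysis stage.

The scoring convention is fixed package-wide: match +1, mismatch -2, and a
gap of length L costs ``gap_open + gap_extend * L`` (default 2 + L).  These
are the classic conservative nucleotide-BLAST reward/penalty settings; all
thresholds elsewhere (minimum score 30, score-difference 4, ...) are stated
on this scale.

Genome-scale placement uses exact k-mer seeding followed by windowed DP
(:class:`GenomeIndex`), so only short reference windows ever enter the
quadratic alignment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio import Align

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

TIE_ENUM_LIMIT = 64


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters; ``gap_open`` is charged once per gap on top of
    ``gap_extend`` per gapped base."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = 2
    gap_extend: int = 1

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = self.match
        aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


DEFAULT_PARAMS = AlignParams()


@dataclass
class Alignment:
    """One local alignment of a query (read) against a reference.

    ``q_start``/``q_end`` are always coordinates on the query as sequenced
    (0-based half-open), regardless of orientation; ``r_start``/``r_end``
    are on the reference forward strand.  ``orientation`` is '+' when the
    query aligns forward, '-' when its reverse complement does.
    """

    q_start: int
    q_end: int
    r_start: int
    r_end: int
    score: float
    orientation: str = "+"
    ref_name: str = ""
    n_mismatch: int = 0
    n_gap: int = 0
    max_gap_len: int = 0
    gap_lengths: list[int] = field(default_factory=list)

    @property
    def q_len(self) -> int:
        return self.q_end - self.q_start

    @property
    def r_len(self) -> int:
        return self.r_end - self.r_start


def _summarize(bio_aln, ref: str, query: str) -> tuple[int, int, list[int]]:
    """Mismatch count and gap lengths from a Biopython alignment path."""
    coords = bio_aln.coordinates  # rows: [target(ref), query]
    n_mm = 0
    gaps: list[int] = []
    for i in range(coords.shape[1] - 1):
        r0, r1 = int(coords[0, i]), int(coords[0, i + 1])
        q0, q1 = int(coords[1, i]), int(coords[1, i + 1])
        if r1 > r0 and q1 > q0:  # aligned block
            for a, b in zip(ref[r0:r1], query[q0:q1]):
                if a != b:
                    n_mm += 1
        elif r1 > r0:  # deletion from query (gap in query)
            gaps.append(r1 - r0)
        elif q1 > q0:  # insertion in query (gap in reference)
            gaps.append(q1 - q0)
    return n_mm, len(gaps), gaps


def local_align(
    query: str,
    ref: str,
    params: AlignParams = DEFAULT_PARAMS,
    ref_name: str = "",
) -> Alignment | None:
    """Best local alignment of ``query`` (forward strand) against ``ref``.

    Among co-optimal alignments the one with the leftmost query start, then
    leftmost reference start, is returned (enumeration capped at
    ``TIE_ENUM_LIMIT`` co-optima, which keeps the choice deterministic even
    for homopolymer queries with astronomically many optimal placements).
    Returns ``None`` when the sequences share no positive-scoring local
    alignment.
    """
    if not query or not ref:
        return None
    aligner = params.make_aligner()
    try:
        alns = aligner.align(ref, query)
    except (ValueError, OverflowError):
        return None
    best = None
    best_key = None
    for bio_aln in itertools.islice(alns, TIE_ENUM_LIMIT):
        if bio_aln.score <= 0:
            break
        coords = bio_aln.coordinates
        r_start, r_end = int(coords[0, 0]), int(coords[0, -1])
        q_start, q_end = int(coords[1, 0]), int(coords[1, -1])
        key = (q_start, r_start)
        if best is None or key < best_key:
            n_mm, n_gap, gaps = _summarize(bio_aln, ref, query)
            best = Alignment(
                q_start=q_start,
                q_end=q_end,
                r_start=r_start,
                r_end=r_end,
                score=float(bio_aln.score),
                orientation="+",
                ref_name=ref_name,
                n_mismatch=n_mm,
                n_gap=n_gap,
                max_gap_len=max(gaps) if gaps else 0,
                gap_lengths=gaps,
            )
            best_key = key
    return best


def best_local_alignment(
    query: str,
    ref: str,
    params: AlignParams = DEFAULT_PARAMS,
    ref_name: str = "",
    both_strands: bool = True,
) -> Alignment | None:
    """Strand-aware best local alignment; ties favor the forward strand.

    Minus-strand hits report query coordinates on the read as sequenced.
    """
    fwd = local_align(query, ref, params, ref_name)
    if not both_strands:
        return fwd
    rc = local_align(revcomp(query), ref, params, ref_name)
    if rc is not None:
        n = len(query)
        rc = Alignment(
            q_start=n - rc.q_end,
            q_end=n - rc.q_start,
            r_start=rc.r_start,
            r_end=rc.r_end,
            score=rc.score,
            orientation="-",
            ref_name=ref_name,
            n_mismatch=rc.n_mismatch,
            n_gap=rc.n_gap,
            max_gap_len=rc.max_gap_len,
            gap_lengths=rc.gap_lengths,
        )
    if fwd is None:
        return rc
    if rc is None or fwd.score >= rc.score:
        return fwd
    return rc


class GenomeIndex:
    """Exact k-mer index over a multi-chromosome genome for seeded local
    alignment.  Seeds are clustered by diagonal; each cluster defines a
    reference window that is aligned with the full affine DP, so reported
    scores follow the package scoring contract exactly."""

    def __init__(self, genome: dict[str, str], k: int = 13, margin: int = 60):
        self.genome = genome
        self.k = k
        self.margin = margin
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.items():
            for pos in range(0, len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                self._index.setdefault(kmer, []).append((chrom, pos))

    LONG_QUERY = 600  # above this, windows are resolved by exact-run matching

    def _seed_windows(
        self, query: str
    ) -> dict[tuple[str, int, int], list[tuple[int, int]]]:
        """Candidate windows with their seed hits: {(chrom, lo, hi):
        [(qpos, rpos), ...]} clustered by alignment diagonal."""
        k = self.k
        n = len(query)
        clusters: dict[tuple[str, int], list[tuple[int, int]]] = {}
        stride = max(1, k // 2)
        starts = list(range(0, max(1, n - k + 1), stride))
        if n >= k and starts[-1] != n - k:
            starts.append(n - k)
        band = 2 * self.margin
        for qpos in starts:
            kmer = query[qpos : qpos + k]
            for chrom, rpos in self._index.get(kmer, ()):
                diag = rpos - qpos
                clusters.setdefault((chrom, diag // band), []).append((qpos, rpos))
        out: dict[tuple[str, int, int], list[tuple[int, int]]] = {}
        for (chrom, _), hits in clusters.items():
            diags = [r - q for q, r in hits]
            lo = min(diags) - self.margin
            hi = max(diags) + n + self.margin
            clen = len(self.genome[chrom])
            key = (chrom, max(0, lo), min(clen, hi))
            out.setdefault(key, []).extend(hits)
        return out

    def _align_window(
        self,
        query: str,
        chrom: str,
        lo: int,
        hi: int,
        hits: list[tuple[int, int]],
        params: AlignParams,
    ) -> Alignment | None:
        """Best placement of the (oriented) query in one window.

        Exact full-length matches short-circuit the DP.  Queries longer
        than ``LONG_QUERY`` (event-scale fragments rather than reads) are
        resolved by maximal exact seed extension per diagonal — the affine
        DP would give the same placement, since crossing a splice or
        junction boundary never pays at these scales."""
        window = self.genome[chrom][lo:hi]
        n = len(query)
        j = window.find(query)
        if j >= 0:
            return Alignment(0, n, lo + j, lo + j + n, float(n), "+", chrom)
        if n > self.LONG_QUERY:
            best: tuple[int, int, int] | None = None  # (run_len, qs, rs)
            seen_diags: set[int] = set()
            for qpos, rpos in hits:
                diag = rpos - qpos
                if diag in seen_diags:
                    continue
                seen_diags.add(diag)
                gseq = self.genome[chrom]
                glen = len(gseq)
                a, b = qpos, rpos
                while a > 0 and b > 0 and query[a - 1] == gseq[b - 1]:
                    a -= 1
                    b -= 1
                c, d = qpos, rpos
                while c < n and d < glen and query[c] == gseq[d]:
                    c += 1
                    d += 1
                run = c - a
                if best is None or run > best[0]:
                    best = (run, a, b)
            if best is None:
                return None
            run, qs, rs = best
            return Alignment(qs, qs + run, rs, rs + run, float(run), "+", chrom)
        aln = local_align(query, window, params, chrom)
        if aln is None:
            return None
        aln.r_start += lo
        aln.r_end += lo
        return aln

    def align(
        self,
        query: str,
        params: AlignParams = DEFAULT_PARAMS,
        both_strands: bool = True,
    ) -> list[Alignment]:
        """All candidate placements of ``query``, best-per-window, sorted by
        descending score (ties: chrom, position).  Overlapping windows from
        the two strands are kept separately."""
        candidates: list[Alignment] = []
        queries = [("+", query)]
        if both_strands:
            queries.append(("-", revcomp(query)))
        for strand, q in queries:
            windows = self._seed_windows(q)
            for (chrom, lo, hi) in sorted(windows):
                aln = self._align_window(q, chrom, lo, hi, windows[(chrom, lo, hi)], params)
                if aln is None:
                    continue
                n = len(query)
                q_start, q_end = aln.q_start, aln.q_end
                if strand == "-":
                    q_start, q_end = n - aln.q_end, n - aln.q_start
                candidates.append(
                    Alignment(
                        q_start=q_start,
                        q_end=q_end,
                        r_start=aln.r_start,
                        r_end=aln.r_end,
                        score=aln.score,
                        orientation=strand,
                        ref_name=chrom,
                        n_mismatch=aln.n_mismatch,
                        n_gap=aln.n_gap,
                        max_gap_len=aln.max_gap_len,
                        gap_lengths=aln.gap_lengths,
                    )
                )
        # merge duplicate placements (same locus found via both windows)
        uniq: dict[tuple[str, str, int, int], Alignment] = {}
        for aln in candidates:
            key = (aln.ref_name, aln.orientation, aln.r_start, aln.r_end)
            if key not in uniq or aln.score > uniq[key].score:
                uniq[key] = aln
        out = sorted(
            uniq.values(),
            key=lambda a: (-a.score, a.ref_name, a.r_start, a.orientation),
        )
        return out
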