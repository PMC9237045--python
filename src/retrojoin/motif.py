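"""Pre-integration consensus-motif analytics.

Canonical L1 integration starts with an endonuclease nick at the
5'-TT/AAAA-3' consensus; the 11 genomic bases spanning positions -3..+8
around each insertion point are extracted on the strand where a canonical
event reads 5'-TT AAAAA-3' across the nick (minus-strand insertions are
reverse-complemented).  Position 0 is the first base 3' of the junction on
the motif strand; -3..-1 are the three bases 5' of it::

        -3 -2 -1 | 0 +1 +2 +3 +4 +5 +6 +7
         N  T  T |  A  A  A  A  A  N  N  N      (canonical TPRT site)
                 ^ insertion point (between-base)

A position-weight matrix over a set of flanks uses plug-in column
frequencies (no pseudocounts); per-column information content is
``2 + sum_b p_b log2 p_b`` bits (uniform background, 0*log0 = 0), and the
motif score is the sum of the information content over the 11 positions.
Chromosome-wide structure is summarized by scoring consecutive windows of
30 insertions and interpolating the window scores with a natural cubic
spline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .align import revcomp

FLANK_UP = 3
FLANK_DOWN = 8
FLANK_LEN = FLANK_UP + FLANK_DOWN
WINDOW_SIZE = 30
_ROW = {"A": 0, "C": 1, "G": 2, "T": 3}


def extract_flank(genome: dict[str, str], chrom: str, pos: int, strand: str = "+") -> str | None:
    """The 11-mer covering positions -3..+8 around the insertion point, on
    the motif strand; None when the window leaves the contig."""
    seq = genome[chrom]
    if strand == "+":
        if pos - FLANK_UP < 0 or pos + FLANK_DOWN > len(seq):
            return None
        return seq[pos - FLANK_UP : pos + FLANK_DOWN]
    if pos - FLANK_DOWN < 0 or pos + FLANK_UP > len(seq):
        return None
    return revcomp(seq[pos - FLANK_DOWN : pos + FLANK_UP])


@dataclass
class PWMWindow:
    region: tuple[int, int]  # genomic span of the contributing insertions
    n: int
    matrix: np.ndarray  # 4 x 11, rows A,C,G,T, columns -3..+8
    ic: np.ndarray  # information content per column, bits
    motif_score: float

    @property
    def center(self) -> float:
        return 0.5 * (self.region[0] + self.region[1])


def build_pwm(flanks: list[str], region: tuple[int, int] = (0, 0)) -> PWMWindow:
    """PWM, per-position information content and summed motif score for a
    set of -3..+8 flanks.  Flanks containing non-ACGT characters are
    dropped; an empty set is an error."""
    clean = [f for f in flanks if len(f) == FLANK_LEN and set(f) <= set("ACGT")]
    if not clean:
        raise ValueError("no usable flanks (need 11-mers over ACGT)")
    counts = np.zeros((4, FLANK_LEN), dtype=float)
    for f in clean:
        for j, base in enumerate(f):
            counts[_ROW[base], j] += 1
    probs = counts / counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
    ic = 2.0 + plogp.sum(axis=0)
    return PWMWindow(
        region=region,
        n=len(clean),
        matrix=probs,
        ic=ic,
        motif_score=float(ic.sum()),
    )


def consensus(window: PWMWindow) -> str:
    """Per-column argmax base (ties broken alphabetically)."""
    return "".join("ACGT"[i] for i in np.argmax(window.matrix, axis=0))


def window_scores(
    positions_strands: list[tuple[int, str]],
    genome: dict[str, str],
    chrom: str,
    window_size: int = WINDOW_SIZE,
) -> list[PWMWindow]:
    """Motif scores over consecutive non-overlapping windows of exactly
    ``window_size`` insertions on one chromosome (input must be position-
    sorted; a trailing partial window is dropped)."""
    windows: list[PWMWindow] = []
    for start in range(0, len(positions_strands) - window_size + 1, window_size):
        chunk = positions_strands[start : start + window_size]
        flanks = []
        for pos, strand in chunk:
            f = extract_flank(genome, chrom, pos, strand)
            if f is not None:
                flanks.append(f)
        if not flanks:
            continue
        region = (chunk[0][0], chunk[-1][0])
        windows.append(build_pwm(flanks, region))
    return windows


def spline_curve(windows: list[PWMWindow]) -> CubicSpline:
    """Natural cubic interpolating spline through (window center, motif
    score); passes through every point.  Needs >= 2 windows with distinct
    centers."""
    if len(windows) < 2:
        raise ValueError("spline interpolation needs at least 2 windows")
    pts = sorted((w.center, w.motif_score) for w in windows)
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    keep = np.concatenate(([True], np.diff(xs) > 0))
    xs, ys = xs[keep], ys[keep]
    if len(xs) < 2:
        raise ValueError("spline interpolation needs >= 2 distinct centers")
    return CubicSpline(xs, ys, bc_type="natural")
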