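"""Independent quadratic-time Gotoh local-alignment oracle used to check
the package's aligner.  Deliberately written as a plain dynamic program
with no shared code: match +1, mismatch -2, a gap of length L costs
2 + L (affine: open 2 charged once, extend 1 per base)."""


def dp_local_score(
    query: str,
    ref: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = 2,
    gap_extend: int = 1,
) -> int:
    n, m = len(query), len(ref)
    NEG = -(10**9)
    first_gap = gap_open + gap_extend
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (consumes ref)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref (consumes query)
    best = 0
    for i in range(1, n + 1):
        qi = query[i - 1]
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first_gap, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first_gap, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + (match if qi == ref[j - 1] else mismatch)
            H[i][j] = max(0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best
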