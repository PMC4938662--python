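"""Independent test oracles, written before the implementations they check.

These deliberately use the slowest, most transparent formulation available
(full Gotoh matrices in pure Python, direct formula evaluation) so they
share no code path with the package.
"""

from __future__ import annotations

import math

NEG = float("-inf")


def gotoh_global_score(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> float:
    """Optimal global affine-gap alignment score by exhaustive DP.

    Gap of length L costs gap_open + (L-1)*gap_extend; end gaps are
    penalized with the same scheme.
    """
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Iy[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            Ix[i][j] = max(M[i - 1][j] + gap_open, Ix[i - 1][j] + gap_extend, Iy[i - 1][j] + gap_open)
            Iy[i][j] = max(M[i][j - 1] + gap_open, Iy[i][j - 1] + gap_extend, Ix[i][j - 1] + gap_open)
    return max(M[n][m], Ix[n][m], Iy[n][m])


def k2p_by_hand(aligned_a: str, aligned_b: str) -> float:
    """K = -1/2 ln((1-2P-Q) sqrt(1-2Q)) evaluated directly from counts."""
    ts = tv = n = 0
    purines = {"A", "G"}
    for x, y in zip(aligned_a, aligned_b):
        if x in "-N" or y in "-N":
            continue
        n += 1
        if x == y:
            continue
        if (x in purines) == (y in purines):
            ts += 1
        else:
            tv += 1
    p, q = ts / n, tv / n
    return -0.5 * math.log((1 - 2 * p - q) * math.sqrt(1 - 2 * q))


def three_point_branch_lengths(dab: float, dac: float, dbc: float) -> tuple[float, float, float]:
    """Closed-form star-tree branch lengths for three taxa."""
    a = (dab + dac - dbc) / 2
    b = (dab + dbc - dac) / 2
    c = (dac + dbc - dab) / 2
    return a, b, c
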