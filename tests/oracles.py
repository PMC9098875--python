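"""Independent reference implementations used only as test oracles.

These are deliberately naive and written without reference to the package
internals: a full-matrix quadratic Gotoh dynamic program, and a brute-force
enumerator of gap-free local alignments.
"""

from __future__ import annotations

NEG = float("-inf")


def sw_oracle(a: str, b: str, match: float, mismatch: float,
              gap_open: float, gap_extend: float) -> float:
    """Quadratic full-matrix affine-gap local alignment score.

    Gap of length L costs gap_open + L * gap_extend (first gap position
    already pays both the opening and one extension).
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return 0.0
    first = gap_open + gap_extend
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - first, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - first, F[i][j - 1] - gap_extend)
            s = match if a[i - 1] == b[j - 1] and a[i - 1] != "N" else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def gapfree_oracle(a: str, b: str, match: float, mismatch: float) -> float:
    """Best gap-free local alignment score by exhaustive enumeration."""
    best = 0.0
    for i in range(len(a)):
        for j in range(len(b)):
            score = 0.0
            for k in range(min(len(a) - i, len(b) - j)):
                score += match if a[i + k] == b[j + k] else mismatch
                best = max(best, score)
    return best
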