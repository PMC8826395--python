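"""Independent oracles used by the tests.

These deliberately reimplement, by the most transparent route available,
quantities the package computes by faster or library-backed means: a full
three-matrix affine-gap Smith-Waterman DP, an exhaustive global-alignment
enumerator for tiny strings, and a dictionary-based k-mer counter.  They are
kept free of any hgtscan internals beyond plain data (substitution scores).
"""

from __future__ import annotations



NEG = float("-inf")


def sw_affine_score(a: str, b: str, score, gap_open: float, gap_extend: float) -> int:
    """Optimal local alignment score; a gap of length L costs open + L*extend.

    ``score(x, y)`` returns the substitution score.  Full O(nm) DP with
    separate match/gap-in-a/gap-in-b matrices; no pruning, no traceback.
    """
    n, m = len(a), len(b)
    best = 0.0
    H = [[0.0] * (m + 1) for _ in range(n + 1)]   # best alignment ending at i,j
    E = [[NEG] * (m + 1) for _ in range(n + 1)]   # ending with a gap in a
    F = [[NEG] * (m + 1) for _ in range(n + 1)]   # ending with a gap in b
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - (gap_open + gap_extend),
                          E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - (gap_open + gap_extend),
                          F[i - 1][j] - gap_extend)
            diag = max(H[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1])
            H[i][j] = max(0.0, diag + score(a[i - 1], b[j - 1]))
            best = max(best, H[i][j], E[i][j], F[i][j])
    return int(round(best))


def nw_best_identity(a: str, b: str, match: float = 1.0, mismatch: float = 0.0,
                     gap_open: float = 10.0, gap_extend: float = 0.5):
    """Enumerate every global alignment of two tiny strings.

    Returns (best score, percent identity of the best-scoring alignment).
    Exponential; only usable for strings of length <= ~6.
    """

    def expand(i, j, cols):
        if i == len(a) and j == len(b):
            yield cols
            return
        if i < len(a) and j < len(b):
            yield from expand(i + 1, j + 1, cols + [(a[i], b[j])])
        if i < len(a):
            yield from expand(i + 1, j, cols + [(a[i], "-")])
        if j < len(b):
            yield from expand(i, j + 1, cols + [(b[j], "-")[::-1]])

    def score_alignment(cols):
        s = 0.0
        ident = 0
        gap_run = None   # which sequence the open gap is in
        for x, y in cols:
            if x == "-" or y == "-":
                which = 0 if x == "-" else 1
                if gap_run == which:
                    s -= gap_extend
                else:
                    s -= gap_open + gap_extend
                gap_run = which
            else:
                gap_run = None
                s += match if x == y else mismatch
                ident += x == y
        return s, 100.0 * ident / len(cols)

    best = max((score_alignment(c) for c in expand(0, 0, [])),
               key=lambda t: t[0])
    return best


def naive_kmer_counts(seq: str, k: int) -> dict[str, int]:
    """Dictionary count of A/C/G/T-only k-mers (windows containing N skipped)."""
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        word = seq[i:i + k]
        if set(word) <= set("ACGT"):
            counts[word] = counts.get(word, 0) + 1
    return counts
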