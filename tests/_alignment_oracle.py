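"""Independent alignment-scoring oracles for testing global_align.

Two implementations that share nothing with the package's Biopython-backed
route:

* ``gotoh_score`` — an iterative three-matrix affine-gap dynamic program
  with free end gaps (gap of internal length L costs open + (L-1)*extend).
* ``enumerate_score`` — brute-force enumeration of every global alignment
  path, scoring each directly from the gapped strings.  Exponential; only
  usable for very short sequences, where it validates the DP.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

NEG = float("-inf")


def _submat(matrix: str = "BLOSUM62"):
    return substitution_matrices.load(matrix)


def gotoh_score(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Affine-gap global alignment score with free end gaps (maximizing)."""
    sub = _submat(matrix)
    n, m = len(a), len(b)
    # M: a[i-1]~b[j-1]; X: gap in a (consumes b); Y: gap in b (consumes a)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for j in range(1, m + 1):
        X[0][j] = 0.0  # free leading gap in a
    for i in range(1, n + 1):
        Y[i][0] = 0.0  # free leading gap in b
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(
                M[i][j - 1] - gap_open,
                X[i][j - 1] - gap_extend,
                Y[i][j - 1] - gap_open,
            )
            Y[i][j] = max(
                M[i - 1][j] - gap_open,
                Y[i - 1][j] - gap_extend,
                X[i - 1][j] - gap_open,
            )
    best = NEG
    for i in range(n + 1):  # free trailing gap in b
        best = max(best, M[i][m], X[i][m], Y[i][m])
    for j in range(m + 1):  # free trailing gap in a
        best = max(best, M[n][j], X[n][j], Y[n][j])
    return best


def score_gapped_pair(
    ga: str,
    gb: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Score one explicit gapped alignment; end gap segments are free."""
    sub = _submat(matrix)
    assert len(ga) == len(gb)
    total = 0.0
    i = 0
    L = len(ga)
    while i < L:
        if ga[i] != "-" and gb[i] != "-":
            total += sub[ga[i], gb[i]]
            i += 1
            continue
        gap_in_a = ga[i] == "-"
        j = i
        while j < L and ((ga[j] == "-") if gap_in_a else (gb[j] == "-")):
            j += 1
        if not (i == 0 or j == L):  # end-gap runs are free
            total -= gap_open + (j - i - 1) * gap_extend
        i = j
    return total


def enumerate_score(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Exhaustive max score over every global alignment path of a and b."""
    best = NEG
    stack = [(0, 0, "", "")]
    while stack:
        i, j, ga, gb = stack.pop()
        if i == len(a) and j == len(b):
            best = max(best, score_gapped_pair(ga, gb, matrix, gap_open, gap_extend))
            continue
        if i < len(a) and j < len(b):
            stack.append((i + 1, j + 1, ga + a[i], gb + b[j]))
        if i < len(a):
            stack.append((i + 1, j, ga + a[i], gb + "-"))
        if j < len(b):
            stack.append((i, j + 1, ga + "-", gb + b[j]))
    return best
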