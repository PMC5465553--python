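"""Brute-force quadratic Smith-Waterman oracle, coded independently.

Plain-Python three-matrix affine-gap local alignment used only to verify
the package aligner.  Conventions mirror the documented contract: BLOSUM62
scoring; a gap of length L costs open + (L-1)*extend; traceback ties
prefer diagonal, then gap-in-query, then gap-in-target, with E/F states
preferring to open; the start cell is the first row-major maximum.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_M = substitution_matrices.load("BLOSUM62")
NEG = float("-inf")


def oracle_align(query: str, target: str, gap_open: int = 11, gap_extend: int = 1):
    """Return (score, identity, coverage) by full dynamic programming."""
    m, n = len(query), len(target)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + _M[query[i - 1], target[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])

    best, bi, bj = 0.0, 0, 0
    for i in range(m + 1):
        for j in range(n + 1):
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    if best <= 0:
        return 0, 0.0, 0.0

    i, j, state = bi, bj, "H"
    matches = columns = q_res = 0
    while True:
        if state == "H":
            if H[i][j] == 0:
                break
            diag = H[i - 1][j - 1] + _M[query[i - 1], target[j - 1]]
            if H[i][j] == diag:
                columns += 1
                q_res += 1
                if query[i - 1] == target[j - 1]:
                    matches += 1
                i, j = i - 1, j - 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            columns += 1
            from_open = H[i][j - 1] - gap_open
            j -= 1
            if E[i][j + 1] == from_open:
                state = "H"
        else:
            columns += 1
            q_res += 1  # gap in target still consumes a query residue
            from_open = H[i - 1][j] - gap_open
            i -= 1
            if F[i + 1][j] == from_open:
                state = "H"
    return int(best), matches / columns, q_res / m
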