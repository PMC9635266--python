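"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain O(N^2) loops over an explicit recurrence
matrix, deliberately sharing no code with the package's implementations.
"""

from __future__ import annotations

import itertools


def brute_matrix(symbols) -> list[list[bool]]:
    n = len(symbols)
    m = [[False] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j and symbols[i] > 0 and symbols[i] == symbols[j]:
                m[i][j] = True
    return m


def brute_rr(symbols) -> float:
    n = len(symbols)
    if n < 2:
        raise ValueError("N < 2")
    m = brute_matrix(symbols)
    return 100.0 * sum(sum(row) for row in m) / (n * n - n)


def brute_line_points(symbols, min_len: int = 2) -> int:
    """Recurrent cells on maximal diagonal runs of length >= min_len."""
    n = len(symbols)
    m = brute_matrix(symbols)
    total = 0
    for offset in range(-(n - 1), n):
        if offset == 0:
            continue
        cells = [(i, i + offset) for i in range(n)
                 if 0 <= i + offset < n]
        run = 0
        for (i, j) in cells + [(-10, -10)]:  # sentinel flushes final run
            if 0 <= i and m[i][j]:
                run += 1
            else:
                if run >= min_len:
                    total += run
                run = 0
    return total


def brute_det(symbols, min_len: int = 2) -> float | None:
    m = brute_matrix(symbols)
    n_points = sum(sum(row) for row in m)
    if n_points == 0:
        return None
    return 100.0 * brute_line_points(symbols, min_len) / n_points


def exact_permutation_p(symbols, min_len: int = 2) -> float | None:
    """Exact upper-tail p over all distinct arrangements (tiny N only)."""
    observed = brute_det(symbols, min_len)
    if observed is None:
        return None
    perms = set(itertools.permutations(symbols))
    ge = sum(1 for p in perms
             if (brute_det(list(p), min_len) or 0.0) >= observed)
    return ge / len(perms)
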