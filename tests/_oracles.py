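"""Independent brute-force reference implementations used only by tests.

Coded with plain Python loops and ``statistics.median`` so they share no code
path (and no vectorization bugs) with the package implementations.
"""

from __future__ import annotations

import math
from statistics import median


def _col(mat, j):
    return [row[j] for row in mat]


def _finite(vals):
    return [v for v in vals if not math.isnan(v)]


def oracle_median_polish(matrix, tol=1e-6, max_iter=100, ls_init=True):
    """Alternating-median polish; returns (overall, row, col, residuals, iters)."""
    z = [[float(v) for v in row] for row in matrix]
    n_rows, n_cols = len(z), len(z[0])
    overall = 0.0
    row_eff = [0.0] * n_rows
    col_eff = [0.0] * n_cols
    if ls_init:
        flat = _finite([v for row in z for v in row])
        overall = sum(flat) / len(flat)
        for i in range(n_rows):
            vals = _finite(z[i])
            row_eff[i] = sum(vals) / len(vals) - overall
        for j in range(n_cols):
            vals = _finite([z[i][j] - row_eff[i] for i in range(n_rows)])
            col_eff[j] = sum(vals) / len(vals) - overall
        for i in range(n_rows):
            for j in range(n_cols):
                z[i][j] = z[i][j] - overall - row_eff[i] - col_eff[j]
    iters = 0
    for iters in range(1, max_iter + 1):
        deltas = []
        for i in range(n_rows):
            m = median(_finite(z[i]))
            for j in range(n_cols):
                z[i][j] -= m
            row_eff[i] += m
            deltas.append(abs(m))
        shift = median(col_eff)
        col_eff = [c - shift for c in col_eff]
        overall += shift
        deltas.append(abs(shift))
        for j in range(n_cols):
            m = median(_finite(_col(z, j)))
            for i in range(n_rows):
                z[i][j] -= m
            col_eff[j] += m
            deltas.append(abs(m))
        shift = median(row_eff)
        row_eff = [r - shift for r in row_eff]
        overall += shift
        deltas.append(abs(shift))
        if max(deltas) < tol:
            break
    return overall, row_eff, col_eff, z, iters


def oracle_average_ranks(values, descending=False):
    """Sort-based average-tie ranks 1..n."""
    vals = [-v for v in values] if descending else list(values)
    order = sorted(range(len(vals)), key=lambda i: vals[i])
    ranks = [0.0] * len(vals)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and vals[order[j + 1]] == vals[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks
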