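"""Rank-product aggregation of replicate B-scores with a permutation null.

Each replicate is ranked separately (rank 1 = most extreme in the tail under
consideration); a gene's rank product is the geometric mean of its K ranks.
Both tails are analyzed: "down" ranks ascending B-scores (hyposecretory
candidates first), "up" ranks descending.  Significance comes from permuted
rank matrices: each permutation draws K independent uniform orderings of
1..n and recomputes all rank products.

p(g)   = (#{permuted rank products <= rp(g)} + 1) / (n_perm * n + 1)
pfp(g) = p(g) * n / rank of g when sorted by rp   (expected false-positive
                                                   proportion)

The +1 pseudo-count keeps permutation p-values strictly positive (a gene can
never look better than the data that produced it).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InputValidationError

RANKPROD_COLUMNS = [
    "gene_id", "rp_down", "rp_up", "p_down", "p_up", "pfp_down", "pfp_up",
]

_MAX_NULL_VALUES = 200_000_000  # overflow/memory guard on n_perm * n_genes


def rank_within_replicate(values, direction: str = "ascending") -> np.ndarray:
    """Ranks 1..n with average-tie handling; descending ranks the negated values."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 1:
        raise InputValidationError("values must be a non-empty 1-D vector")
    if not np.isfinite(values).all():
        raise InputValidationError("non-finite values cannot be ranked")
    if direction == "ascending":
        return rankdata(values, method="average")
    if direction == "descending":
        return rankdata(-values, method="average")
    raise InputValidationError(f"unknown direction {direction!r}")


def rank_product(ranks) -> float:
    """Geometric mean (prod ** 1/K) of a gene's per-replicate ranks."""
    ranks = np.asarray(ranks, dtype=float)
    if ranks.size == 0:
        raise InputValidationError("empty rank vector")
    if (ranks < 1).any():
        raise InputValidationError("ranks must be >= 1")
    return float(np.prod(ranks) ** (1.0 / ranks.size))


def permutation_pvalue(
    rp_observed,
    n_genes: int,
    K: int,
    n_perm: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation p-values and expected false-positive proportions.

    Deterministic under a fixed seed.  Returns ``(p, pfp)`` aligned with
    ``rp_observed``.
    """
    rp_observed = np.asarray(rp_observed, dtype=float)
    if n_perm < 1:
        raise InputValidationError("n_perm must be >= 1")
    if n_genes < 1:
        raise InputValidationError("n_genes must be >= 1")
    if n_perm * n_genes > _MAX_NULL_VALUES:
        raise InputValidationError(
            f"n_perm * n_genes = {n_perm * n_genes} exceeds guard "
            f"({_MAX_NULL_VALUES})"
        )
    if ((rp_observed < 1 - 1e-9) | (rp_observed > n_genes + 1e-9)).any():
        raise InputValidationError("rank products must lie in [1, n_genes]")
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, n_genes))
    for b in range(n_perm):
        prod = np.ones(n_genes)
        for _ in range(K):
            prod *= rng.permutation(n_genes) + 1.0
        null[b] = prod ** (1.0 / K)
    null_sorted = np.sort(null, axis=None)
    # tiny tolerance so float round-off in prod**(1/K) cannot drop exact ties
    counts = np.searchsorted(null_sorted, rp_observed * (1 + 1e-12), side="right")
    p = (counts + 1) / (n_perm * n_genes + 1)
    order_rank = rankdata(rp_observed, method="average")
    pfp = p * n_genes / order_rank
    return p, pfp


def rank_product_analysis(
    b_table: pd.DataFrame, n_perm: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Two-tailed rank-product analysis of a B-score table.

    ``b_table`` needs columns ``gene_id, replicate, b_score``.  Genes absent
    from any replicate are dropped (ranking requires a complete matrix).
    """
    required = {"gene_id", "replicate", "b_score"}
    if not required <= set(b_table.columns):
        raise InputValidationError(f"b-score table needs columns {sorted(required)}")
    if len(b_table) == 0:
        raise InputValidationError("empty b-score table")
    wide = b_table.pivot_table(
        index="gene_id", columns="replicate", values="b_score", aggfunc="first"
    ).dropna()
    n = len(wide)
    if n == 0:
        raise InputValidationError("no gene has b-scores in every replicate")
    K = wide.shape[1]
    mat = wide.to_numpy()
    ranks_down = np.column_stack(
        [rank_within_replicate(mat[:, k], "ascending") for k in range(K)]
    )
    ranks_up = np.column_stack(
        [rank_within_replicate(mat[:, k], "descending") for k in range(K)]
    )
    rp_down = np.prod(ranks_down, axis=1) ** (1.0 / K)
    rp_up = np.prod(ranks_up, axis=1) ** (1.0 / K)
    p_down, pfp_down = permutation_pvalue(rp_down, n, K, n_perm, seed)
    p_up, pfp_up = permutation_pvalue(rp_up, n, K, n_perm, seed)
    return pd.DataFrame(
        {
            "gene_id": wide.index,
            "rp_down": rp_down,
            "rp_up": rp_up,
            "p_down": p_down,
            "p_up": p_up,
            "pfp_down": pfp_down,
            "pfp_up": pfp_up,
        }
    ).reset_index(drop=True)
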