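"""Alpha-restricted robust rank aggregation (α-RRA) with a permutation null.

All values (variance-adjusted residuals, or single-guide log2 fold changes)
are pooled and ranked ascending — rank 1 is the most depleted — and
converted to normalized ranks u = rank/N (ties receive average ranks).
For a group owning n of the N values, the members with u <= alpha are kept;
with their sorted normalized ranks u(1) <= ... <= u(k) the score is

    rho = min_{j=1..k}  BetaCDF(u(j); j, n - j + 1),

the smallest tail probability that j of n uniform order statistics would
sit this low by chance.  Groups with no value in the bottom alpha fraction
score rho = 1.  Significance is assessed by permutation: rank sets of size
n are repeatedly reassigned at random from the pool and the fraction of
null scores at or below the observed one is reported (never below
1/(n_perm + 1)).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import betainc
from scipy.stats import rankdata

__all__ = ["rra_score", "alpha_rra", "alpha_rra_groups"]


def rra_score(u: np.ndarray, n: int, alpha: float) -> float:
    """ρ for one group's normalized ranks ``u`` (its full set of n ranks)."""
    u = np.sort(np.asarray(u, dtype=float))
    keep = u <= alpha
    if not keep.any():
        return 1.0
    k = int(keep.sum())
    j = np.arange(1, k + 1, dtype=float)
    return float(np.min(betainc(j, n - j + 1, u[:k])))


def _rho_matrix(U: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorized ρ for rows of U, each a group's n normalized ranks."""
    U = np.sort(U, axis=1)
    m, n = U.shape
    j = np.arange(1, n + 1, dtype=float)
    B = betainc(j[None, :], n - j[None, :] + 1, U)
    B = np.where(U <= alpha, B, 1.0)
    rho = B.min(axis=1)
    return np.where((U <= alpha).any(axis=1), rho, 1.0)


def alpha_rra_groups(values: np.ndarray, groups: np.ndarray,
                     alpha: float = 0.10, n_perm: int = 10_000,
                     seed: int | None = None) -> pd.DataFrame:
    """α-RRA over arbitrary groups of pooled values.

    Returns a DataFrame indexed by group with columns n, k, rho, p.
    ``n_perm`` is the number of null scores drawn per group size; the
    permutation reassigns whole rank sets, so values within a group are
    treated as exchangeable with the pool.
    """
    if not (0 < alpha <= 0.5):
        raise ValueError("alpha must lie in (0, 0.5]")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for an interpretable p")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    N = len(values)
    if N == 0 or len(groups) != N:
        raise ValueError("values and groups must be equal-length, non-empty")

    u = rankdata(values, method="average") / N

    labels, inv = np.unique(groups, return_inverse=True)
    sizes = np.bincount(inv)
    rho_obs = np.empty(len(labels))
    for gi in range(len(labels)):
        ui = u[inv == gi]
        rho_obs[gi] = rra_score(ui, sizes[gi], alpha)
        # k recorded below

    k_obs = np.array([(u[inv == gi] <= alpha).sum()
                      for gi in range(len(labels))])

    # permutation null, pooled per distinct group size
    rng = np.random.default_rng(seed)
    distinct = np.unique(sizes)
    group_count = {n: int((sizes == n).sum()) for n in distinct}
    null: dict[int, list[np.ndarray]] = {int(n): [] for n in distinct}
    have = dict.fromkeys(null, 0)
    # each shuffle reassigns every group at once; sizes with many groups
    # reach their quota quickly
    offsets = np.concatenate([[0], np.cumsum(np.sort(sizes))])
    size_sorted = np.sort(sizes)
    while any(have[n] < n_perm for n in have):
        perm = rng.permutation(u)
        for n in distinct:
            n = int(n)
            if have[n] >= n_perm:
                continue
            sel = np.flatnonzero(size_sorted == n)
            rows = np.stack([perm[offsets[i]:offsets[i + 1]] for i in sel])
            null[n].append(_rho_matrix(rows, alpha))
            have[n] += len(sel)

    p = np.empty(len(labels))
    for gi, n in enumerate(sizes):
        pool = np.concatenate(null[int(n)])
        p[gi] = (1 + (pool <= rho_obs[gi]).sum()) / (len(pool) + 1)

    return pd.DataFrame({"n": sizes, "k": k_obs, "rho": rho_obs, "p": p},
                        index=pd.Index(labels, name="group"))


def alpha_rra(residuals: pd.DataFrame, alpha: float = 0.10,
              n_perm: int = 10_000, seed: int | None = None) -> pd.DataFrame:
    """α-RRA over gene pairs from a variance-adjusted residual table.

    ``residuals`` needs columns ``gene_pair`` and ``adjusted_residual``
    (all paired constructs x comparisons pooled).  Returns a DataFrame
    indexed by gene_pair with columns n, k, rho, p.
    """
    vals = residuals["adjusted_residual"].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("adjusted residuals must be finite; run "
                         "variance_adjust first")
    out = alpha_rra_groups(vals, residuals["gene_pair"].to_numpy(),
                           alpha=alpha, n_perm=n_perm, seed=seed)
    out.index.name = "gene_pair"
    return out
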