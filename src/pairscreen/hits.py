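"""Synthetic-lethal hit calling from variance-adjusted residuals.

A gene pair is a hit only when two independent tests agree: a one-sample
t statistic on its pooled variance-adjusted residuals,

    t = mean(r) / sqrt( var(r) / (n - 1) ),

with var the unbiased sample variance and a two-sided p from the t
distribution with n - 1 degrees of freedom, and the α-RRA permutation test
on the bottom 10% of pooled residual ranks.  Both p-value families are
Bonferroni-corrected across the tested pair universe and thresholded at
0.1; a hit additionally requires a negative mean adjusted residual and must
not contain a gene that is lethal in isolation (such genes show enhanced
activity in the hU6 slot, inflating pair residuals for reasons unrelated to
genetic interaction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .library import GuideLibrary
from .quantify import FoldChangeTable
from .rra import alpha_rra_groups

__all__ = ["PairResult", "EssentialGeneSet", "pair_t_test", "pair_t_table",
           "adjust_and_call", "call_single_gene_depletion", "filter_hits",
           "competitive_assay_residual"]

RESULT_COLUMNS = ["gene_pair", "n_residuals", "mean_adjusted_residual",
                  "t_stat", "t_p", "t_p_adj", "rra_rho", "rra_p",
                  "rra_p_adj", "significant_t", "significant_rra", "is_hit",
                  "filter_reason"]


@dataclass(frozen=True)
class PairResult:
    gene_pair: str
    n_residuals: int
    mean_adjusted_residual: float
    t_stat: float
    t_p: float
    t_p_adj: float
    rra_rho: float
    rra_p: float
    rra_p_adj: float
    significant_t: bool
    significant_rra: bool
    is_hit: bool
    filter_reason: str = "none"


@dataclass
class EssentialGeneSet:
    """Genes lethal in isolation, with per-gene provenance
    ("internal_day14" from this screen's own day-14 depletion call, or
    "external_list" from a user-supplied list)."""

    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def genes(self) -> set[str]:
        return set(self.provenance)

    def merge_external(self, genes) -> "EssentialGeneSet":
        for g in genes:
            self.provenance.setdefault(g, "external_list")
        return self

    def to_tsv(self, path) -> None:
        pd.DataFrame(sorted(self.provenance.items()),
                     columns=["gene", "provenance"]).to_csv(
            path, sep="\t", index=False)


def pair_t_test(residuals) -> tuple[float, float]:
    """t and two-sided p for one pair's adjusted residuals.

    t = mean / sqrt(var / (n - 1)); note the n - 1 (not n) in the
    denominator.  Degrees of freedom n - 1.  Returns (nan, nan) when n < 3
    or the variance is zero (callers flag such pairs instead of raising).
    """
    r = np.asarray(residuals, dtype=float)
    n = len(r)
    if n < 3:
        return (np.nan, np.nan)
    var = r.var(ddof=1)
    if var == 0:
        return (np.nan, np.nan)
    t = r.mean() / np.sqrt(var / (n - 1))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return (float(t), float(p))


def pair_t_table(residuals: pd.DataFrame) -> pd.DataFrame:
    """Per-pair t statistics from a variance-adjusted residual table."""
    rows = []
    for pair, sub in residuals.groupby("gene_pair", sort=True):
        r = sub["adjusted_residual"].to_numpy(dtype=float)
        t, p = pair_t_test(r)
        rows.append({"gene_pair": pair, "n_residuals": len(r),
                     "mean_adjusted_residual": r.mean() if len(r) else np.nan,
                     "t_stat": t, "t_p": p})
    return pd.DataFrame(rows).set_index("gene_pair")


def adjust_and_call(t_table: pd.DataFrame, rra_table: pd.DataFrame,
                    method: str = "bonferroni",
                    threshold: float = 0.1) -> pd.DataFrame:
    """Multiple-testing correction and the dual-test hit decision.

    Bonferroni (default, the literal procedure: adjusted p = min(1, p*m)
    thresholded at 0.1) or Benjamini-Hochberg.  A hit needs both adjusted
    p-values under the threshold, a negative mean adjusted residual, and no
    filter; pairs whose t test was undefined are flagged
    insufficient_residuals.
    """
    if method not in ("bonferroni", "bh"):
        raise ValueError(f"unknown correction method {method!r}")
    if set(t_table.index) != set(rra_table.index):
        raise ValueError("t and RRA tables cover different pair universes")
    rra_table = rra_table.reindex(t_table.index)
    m = len(t_table)

    def _adjust(p: np.ndarray) -> np.ndarray:
        if method == "bonferroni":
            return np.minimum(1.0, p * m)
        order = np.argsort(p)
        adj = np.empty_like(p)
        ranked = p[order] * m / np.arange(1, m + 1)
        adj[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        return np.minimum(1.0, adj)

    t_p = t_table["t_p"].to_numpy(dtype=float)
    rra_p = rra_table["p"].to_numpy(dtype=float)
    insufficient = ~np.isfinite(t_p)
    t_p_adj = np.where(insufficient, np.nan, _adjust(np.where(insufficient,
                                                              1.0, t_p)))
    rra_p_adj = _adjust(rra_p)

    sig_t = np.where(insufficient, False, t_p_adj < threshold)
    sig_rra = rra_p_adj < threshold
    mean_neg = t_table["mean_adjusted_residual"].to_numpy() < 0
    out = pd.DataFrame({
        "gene_pair": t_table.index,
        "n_residuals": t_table["n_residuals"].to_numpy(),
        "mean_adjusted_residual": t_table["mean_adjusted_residual"].to_numpy(),
        "t_stat": t_table["t_stat"].to_numpy(),
        "t_p": t_p, "t_p_adj": t_p_adj,
        "rra_rho": rra_table["rho"].to_numpy(),
        "rra_p": rra_p, "rra_p_adj": rra_p_adj,
        "significant_t": sig_t.astype(bool),
        "significant_rra": sig_rra.astype(bool),
        "is_hit": (sig_t & sig_rra & mean_neg & ~insufficient).astype(bool),
        "filter_reason": np.where(insufficient, "insufficient_residuals",
                                  "none"),
    })
    return out.reset_index(drop=True)[RESULT_COLUMNS]


def call_single_gene_depletion(fc: FoldChangeTable, lib: GuideLibrary,
                               alpha: float = 0.10, n_perm: int = 10_000,
                               threshold: float = 0.1,
                               seed: int | None = None,
                               external: set[str] | None = None,
                               correction: str = "bh") -> EssentialGeneSet:
    """Simplified single-construct depletion caller (day-14 screen).

    Summarizes each unflagged single-targeting construct by its mean
    observed log2FC across the crossed comparisons (one value per guide —
    the guide-level ranking unit of MAGeCK-style callers; a guide's nine
    comparisons share samples and are not independent evidence), ranks the
    construct summaries, and applies the α-RRA machinery grouped by
    targeted gene; genes with adjusted p < ``threshold`` are flagged
    lethal in isolation.  The default correction is Benjamini-Hochberg,
    matching the FDR semantics of MAGeCK-style gene depletion calls
    (``correction="bonferroni"`` is available).  An optional external
    essential-gene list is merged with provenance ``external_list``.
    """
    singles = {c.construct_id: lib.guide(c.su6_guide).gene
               for c in lib.single_constructs()}
    sub = fc.df[fc.df["construct_id"].isin(singles)
                & ~fc.df["low_count_flag"]]
    if sub.empty:
        raise ValueError("no single-targeting observations available")
    per_guide = sub.groupby("construct_id")["observed_log2fc"].mean()
    genes = per_guide.index.map(singles).to_numpy()
    table = alpha_rra_groups(per_guide.to_numpy(), genes,
                             alpha=alpha, n_perm=n_perm, seed=seed)
    m = len(table)
    p = table["p"].to_numpy()
    if correction == "bonferroni":
        adj = np.minimum(1.0, p * m)
    elif correction == "bh":
        order = np.argsort(p)
        adj = np.empty_like(p)
        ranked = p[order] * m / np.arange(1, m + 1)
        adj[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.minimum(1.0, adj)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    ess = EssentialGeneSet()
    for gene, p_adj in zip(table.index, adj):
        if p_adj < threshold:
            ess.provenance[str(gene)] = "internal_day14"
    if external:
        ess.merge_external(external)
    return ess


def filter_hits(results: pd.DataFrame,
                ess: EssentialGeneSet) -> pd.DataFrame:
    """Remove pairs containing a gene lethal in isolation from the hit set.

    Statistics are retained; only ``is_hit`` and ``filter_reason`` change.
    """
    out = results.copy()
    if not ess.genes:
        return out
    members = out["gene_pair"].str.split("|", expand=True)
    contains = members[0].isin(ess.genes) | members[1].isin(ess.genes)
    out.loc[contains, "is_hit"] = False
    out.loc[contains, "filter_reason"] = "essential_gene_in_pair"
    return out


def competitive_assay_residual(fractions_t0: dict[str, float],
                               fractions_t1: dict[str, float]) -> float:
    """Interaction residual from a two-colour competitive growth assay.

    ``fractions_*`` map population labels {"untransduced", "a", "b",
    "double"} to FACS fractions summing to 1 at each timepoint.  Each
    transduced population's phenotype is its log2 growth relative to the
    untransduced cells; the residual is the double-positive phenotype minus
    the sum of the two single-positive phenotypes.  Negative means the pair
    is more lethal than additive.
    """
    keys = {"untransduced", "a", "b", "double"}
    for name, frac in (("t0", fractions_t0), ("t1", fractions_t1)):
        if set(frac) != keys:
            raise ValueError(f"{name} must define populations {sorted(keys)}")
        if abs(sum(frac.values()) - 1.0) > 1e-6:
            raise ValueError(f"{name} fractions must sum to 1")
        for pop in keys:
            if frac[pop] <= 0:
                raise ValueError(f"{name}: population {pop!r} has zero "
                                 f"fraction")

    def phenotype(pop: str) -> float:
        return np.log2((fractions_t1[pop] / fractions_t1["untransduced"])
                       / (fractions_t0[pop] / fractions_t0["untransduced"]))

    return float(phenotype("double") - (phenotype("a") + phenotype("b")))
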