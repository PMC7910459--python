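"""Bliss-expectation residual scoring for paired-guide constructs.

Under Bliss independence the expected log2 fold change of a paired
construct is the sum of the observed log2FC of its two guides measured in
single-targeting constructs (each paired with the non-targeting control)
in the same screen-vs-baseline comparison:

    expected(g1g2) = observed(g1) + observed(g2)

Each comparison's population of (expected, observed) points is modelled
with LOESS, which absorbs global effects such as double-cutting toxicity;
a construct's residual is the vertical distance of its observed value from
the fitted curve at its expected value.  Residual variance grows with the
expected lethality of the pair, so residuals are variance-smoothed in bins
of constructs ranked by expected log2FC before testing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .library import GuideLibrary
from .loess import fit_population_loess
from .quantify import Comparison, FoldChangeTable

__all__ = ["ResidualTable", "expected_log2fc", "compute_residuals",
           "variance_adjust"]


class ResidualTable:
    """Per (paired construct, comparison) residual rows.

    Columns: construct_id, gene_pair, comparison_id, expected_log2fc,
    observed_log2fc, fitted_log2fc, residual, adjusted_residual, bin_index.
    ``adjusted_residual`` and ``bin_index`` are NaN/-1 until
    :func:`variance_adjust` has run.
    """

    COLUMNS = ["construct_id", "gene_pair", "comparison_id",
               "expected_log2fc", "observed_log2fc", "fitted_log2fc",
               "residual", "adjusted_residual", "bin_index"]

    def __init__(self, df: pd.DataFrame):
        if list(df.columns) != self.COLUMNS:
            raise ValueError(f"expected columns {self.COLUMNS}")
        resid = df["observed_log2fc"] - df["fitted_log2fc"]
        if not np.allclose(resid, df["residual"], rtol=0, atol=1e-12):
            raise ValueError("residual must equal observed - fitted")
        self.df = df.reset_index(drop=True)

    @property
    def adjusted(self) -> bool:
        return bool(np.isfinite(self.df["adjusted_residual"]).all())

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ResidualTable":
        return cls(pd.read_csv(path, sep="\t")[cls.COLUMNS])


def expected_log2fc(fc: FoldChangeTable, lib: GuideLibrary,
                    comparison_id: str) -> tuple[dict[str, float], list[str]]:
    """Bliss-expected log2FC for every paired construct in one comparison.

    Uses each guide's single-targeting construct observation from the same
    comparison.  Returns (mapping construct_id -> expected, list of paired
    construct_ids excluded because the construct itself or either of its
    single-guide observations is missing or low-count flagged).
    """
    sub = fc.df[fc.df["comparison_id"] == comparison_id]
    if sub.empty:
        raise ValueError(f"comparison {comparison_id!r} absent from the "
                         f"fold-change table")
    obs = dict(zip(sub["construct_id"], sub["observed_log2fc"]))
    flagged = set(sub.loc[sub["low_count_flag"], "construct_id"])

    single_of = {c.su6_guide: c.construct_id for c in lib.single_constructs()}

    expected: dict[str, float] = {}
    excluded: list[str] = []
    for c in lib.paired_constructs():
        cid = c.construct_id
        s1 = single_of.get(c.hu6_guide)
        s2 = single_of.get(c.su6_guide)
        usable = (cid in obs and cid not in flagged
                  and s1 in obs and s1 not in flagged
                  and s2 in obs and s2 not in flagged)
        if not usable:
            excluded.append(cid)
            continue
        expected[cid] = obs[s1] + obs[s2]
    return expected, excluded


def compute_residuals(fc: FoldChangeTable, lib: GuideLibrary,
                      comparisons: list[Comparison], span: float = 0.75,
                      degree: int = 2) -> ResidualTable:
    """LOESS-fit each comparison separately and interpolate residuals.

    One fit per comparison (the nine crossed comparisons are modelled
    independently); residual = observed - fitted(expected).
    """
    lookup = fc.lookup()["observed_log2fc"]
    pair_key = {c.construct_id: lib.pair_of(c).key
                for c in lib.paired_constructs()}
    frames = []
    for comp in comparisons:
        cid = comp.comparison_id
        exp_map, _excluded = expected_log2fc(fc, lib, cid)
        if not exp_map:
            continue
        constructs = sorted(exp_map)
        expected = np.array([exp_map[c] for c in constructs])
        observed = np.array([lookup.loc[(c, cid)] for c in constructs])
        fit = fit_population_loess(expected, observed, span=span,
                                   degree=degree)
        fitted = fit(expected)
        frames.append(pd.DataFrame({
            "construct_id": constructs,
            "gene_pair": [pair_key[c] for c in constructs],
            "comparison_id": cid,
            "expected_log2fc": expected,
            "observed_log2fc": observed,
            "fitted_log2fc": fitted,
            "residual": observed - fitted,
            "adjusted_residual": np.nan,
            "bin_index": -1,
        }))
    if not frames:
        raise ValueError("no comparison produced residuals")
    return ResidualTable(pd.concat(frames, ignore_index=True))


def _bin_edges(n: int, bin_size: int) -> list[tuple[int, int]]:
    """Consecutive [start, stop) bins; a short final bin (< bin_size/4) is
    merged into its neighbour."""
    edges = list(range(0, n, bin_size)) + [n]
    spans = list(zip(edges[:-1], edges[1:]))
    if len(spans) > 1 and (spans[-1][1] - spans[-1][0]) < bin_size / 4:
        a, _ = spans[-2]
        spans = spans[:-2] + [(a, n)]
    return spans


def variance_adjust(rt: ResidualTable, bin_size: int = 200,
                    divisor: str = "variance") -> ResidualTable:
    """Variance-smooth residuals in bins of constructs ranked by expected
    log2FC, separately within each comparison.

    ``divisor="variance"`` divides each residual by its bin's (unbiased)
    variance; ``divisor="sd"`` divides by the bin standard deviation, which
    is the studentizing variant that actually equalizes spread.
    """
    if bin_size < 10:
        raise ValueError("bin_size must be >= 10")
    if divisor not in ("variance", "sd"):
        raise ValueError(f"unknown divisor {divisor!r}")
    df = rt.df.copy()
    adj = np.full(len(df), np.nan)
    bin_idx = np.full(len(df), -1, dtype=int)
    for cid, sub in df.groupby("comparison_id", sort=False):
        order = sub["expected_log2fc"].to_numpy().argsort(kind="stable")
        rows = sub.index.to_numpy()[order]
        resid = df.loc[rows, "residual"].to_numpy()
        for b, (a, z) in enumerate(_bin_edges(len(rows), bin_size)):
            block = resid[a:z]
            var = block.var(ddof=1) if len(block) > 1 else 0.0
            if var == 0:
                raise ValueError(
                    f"zero residual variance in bin {b} of comparison {cid}")
            denom = var if divisor == "variance" else np.sqrt(var)
            adj[rows[a:z]] = block / denom
            bin_idx[rows[a:z]] = b
    df["adjusted_residual"] = adj
    df["bin_index"] = bin_idx
    return ResidualTable(df)
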