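"""Model/Results interface for paired-guide screen analysis.

:class:`PairedScreen` wraps a count matrix and a guide library the way a
statsmodels model wraps endog/exog; :meth:`PairedScreen.fit` runs the full
scoring chain (normalization, crossed comparisons, Bliss expectations,
per-comparison LOESS, binned variance smoothing, the dual t/α-RRA test
with Bonferroni correction, and the lethal-in-isolation filter) and
returns a :class:`PairedScreenResults` carrying every intermediate table,
the per-pair statistics, and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hits import (EssentialGeneSet, adjust_and_call,
                   call_single_gene_depletion, filter_hits, pair_t_table)
from .library import GuideLibrary, load_library
from .quantify import (CountMatrix, FoldChangeTable, compute_log2fc,
                       make_comparisons, normalize_counts)
from .rra import alpha_rra
from .scoring import ResidualTable, compute_residuals, variance_adjust
from .simulate import TrueEffects

__all__ = ["PairedScreen", "PairedScreenResults"]


class PairedScreen:
    """Paired-gRNA screen scoring model.

    Parameters
    ----------
    counts : CountMatrix
        Raw construct x sample counts with sample roles/replicates.
    library : GuideLibrary
        The dual-promoter library the counts refer to.
    screen_timepoint : int
        Day of the screen samples scored for interactions (default 28).
    essential_timepoint : int or None
        Day used for the internal lethal-in-isolation call (default 14;
        None disables the internal call).
    normalization, pseudocount, min_baseline_count
        Depth normalization scheme and low-count flagging for the
        fold-change stage.
    """

    def __init__(self, counts: CountMatrix, library: GuideLibrary,
                 screen_timepoint: int = 28,
                 essential_timepoint: int | None = 14,
                 normalization: str = "median_ratio",
                 pseudocount: float = 1.0,
                 min_baseline_count: int = 30):
        self.counts = counts
        self.library = library
        self.screen_timepoint = screen_timepoint
        self.essential_timepoint = essential_timepoint
        self.normalization = normalization
        self.pseudocount = pseudocount
        self.min_baseline_count = min_baseline_count

    @classmethod
    def from_tables(cls, counts_path, samples_path, library_path,
                    **kwargs) -> "PairedScreen":
        """Build the model from the on-disk TSV formats."""
        return cls(CountMatrix.from_tsv(counts_path, samples_path),
                   load_library(library_path), **kwargs)

    # ------------------------------------------------------------------
    def fold_changes(self, timepoint: int) -> FoldChangeTable:
        normalized = normalize_counts(self.counts, self.normalization,
                                      self.pseudocount)
        comps = make_comparisons(self.counts.samples, timepoint)
        return compute_log2fc(normalized, self.counts, comps,
                              self.min_baseline_count, self.pseudocount)

    def fit(self, span: float = 0.75, degree: int = 2, bin_size: int = 200,
            divisor: str = "variance", alpha: float = 0.10,
            n_perm: int = 10_000, threshold: float = 0.1,
            correction: str = "bonferroni",
            external_essential: set[str] | None = None,
            seed: int | None = None) -> "PairedScreenResults":
        """Run the full scoring chain and return the results object."""
        fc = self.fold_changes(self.screen_timepoint)
        comps = make_comparisons(self.counts.samples, self.screen_timepoint)
        residuals = compute_residuals(fc, self.library, comps, span=span,
                                      degree=degree)
        residuals = variance_adjust(residuals, bin_size=bin_size,
                                    divisor=divisor)
        t_table = pair_t_table(residuals.df)
        rra_table = alpha_rra(residuals.df, alpha=alpha, n_perm=n_perm,
                              seed=seed)
        results = adjust_and_call(t_table, rra_table, method=correction,
                                  threshold=threshold)

        essential = EssentialGeneSet()
        tp = self.essential_timepoint
        has_day14 = tp is not None and any(
            s.role == "screen" and s.timepoint_days == tp
            for s in self.counts.samples)
        if has_day14:
            fc14 = self.fold_changes(tp)
            essential = call_single_gene_depletion(
                fc14, self.library, alpha=alpha, n_perm=n_perm,
                threshold=threshold, external=external_essential,
                seed=None if seed is None else seed + 1)
        elif external_essential:
            essential.merge_external(external_essential)
        results = filter_hits(results, essential)

        params = dict(span=span, degree=degree, bin_size=bin_size,
                      divisor=divisor, alpha=alpha, n_perm=n_perm,
                      threshold=threshold, correction=correction, seed=seed,
                      normalization=self.normalization,
                      pseudocount=self.pseudocount,
                      min_baseline_count=self.min_baseline_count,
                      screen_timepoint=self.screen_timepoint,
                      essential_timepoint=self.essential_timepoint)
        return PairedScreenResults(self, fc, residuals, results, essential,
                                   params)


@dataclass
class PairedScreenResults:
    """Fitted screen: fold changes, residuals, per-pair statistics."""

    model: PairedScreen
    fold_change_table: FoldChangeTable
    residual_table: ResidualTable
    pair_results: pd.DataFrame
    essential_genes: EssentialGeneSet
    params: dict

    @property
    def hits(self) -> pd.DataFrame:
        """Significant synthetic-lethal pairs, most lethal first."""
        h = self.pair_results[self.pair_results["is_hit"]]
        return h.sort_values("mean_adjusted_residual").reset_index(drop=True)

    def confusion(self, truth: TrueEffects) -> dict[str, float]:
        """Sensitivity / false-discovery proportion against ground truth."""
        called = set(self.pair_results.loc[self.pair_results["is_hit"],
                                           "gene_pair"])
        true_sl = truth.sl_pairs
        tp = len(called & true_sl)
        fp = len(called - true_sl)
        fn = len(true_sl - called)
        return {
            "n_true_sl": len(true_sl), "n_called": len(called),
            "true_positives": tp, "false_positives": fp,
            "false_negatives": fn,
            "sensitivity": tp / len(true_sl) if true_sl else float("nan"),
            "fdp": fp / len(called) if called else 0.0,
        }

    def summary(self) -> str:
        """Human-readable summary table, statsmodels-style."""
        pr = self.pair_results
        n_pairs = len(pr)
        n_hits = int(pr["is_hit"].sum())
        n_filtered = int((pr["filter_reason"] == "essential_gene_in_pair")
                         .sum())
        n_insuff = int((pr["filter_reason"] == "insufficient_residuals")
                       .sum())
        lines = [
            "Paired-gRNA screen interaction results",
            "=" * 54,
            f"{'Gene pairs tested':34s}{n_pairs:>20d}",
            f"{'Residual rows':34s}{len(self.residual_table.df):>20d}",
            f"{'Synthetic-lethal hits':34s}{n_hits:>20d}",
            f"{'Filtered (lethal gene in pair)':34s}{n_filtered:>20d}",
            f"{'Insufficient residuals':34s}{n_insuff:>20d}",
            f"{'Essential genes flagged':34s}"
            f"{len(self.essential_genes.genes):>20d}",
            "-" * 54,
            f"LOESS span {self.params['span']}, degree "
            f"{self.params['degree']}; bins of {self.params['bin_size']} "
            f"({self.params['divisor']} divisor)",
            f"alpha-RRA alpha {self.params['alpha']}, "
            f"{self.params['n_perm']} permutations; "
            f"{self.params['correction']} threshold "
            f"{self.params['threshold']}",
        ]
        if n_hits:
            lines.append("-" * 54)
            lines.append(f"{'gene_pair':22s}{'mean adj resid':>14s}"
                         f"{'t_p_adj':>9s}{'rra_p_adj':>10s}")
            for r in self.hits.itertuples():
                lines.append(
                    f"{r.gene_pair:22s}{r.mean_adjusted_residual:>14.3f}"
                    f"{r.t_p_adj:>9.2g}{r.rra_p_adj:>10.2g}")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def to_tsv(self, results_path, residuals_path=None,
               fold_changes_path=None, essential_path=None) -> None:
        self.pair_results.to_csv(results_path, sep="\t", index=False)
        if residuals_path is not None:
            self.residual_table.to_tsv(residuals_path)
        if fold_changes_path is not None:
            self.fold_change_table.to_tsv(fold_changes_path)
        if essential_path is not None:
            self.essential_genes.to_tsv(essential_path)

    def plot_population(self, comparison_id: str, ax=None):
        """Observed vs expected log2FC with the fitted LOESS curve."""
        import matplotlib.pyplot as plt

        sub = self.residual_table.df
        sub = sub[sub["comparison_id"] == comparison_id]
        if sub.empty:
            raise ValueError(f"no residuals for comparison {comparison_id!r}")
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(sub["expected_log2fc"], sub["observed_log2fc"], s=4,
                   alpha=0.3, color="grey", label="paired constructs")
        order = sub.sort_values("expected_log2fc")
        ax.plot(order["expected_log2fc"], order["fitted_log2fc"],
                color="tab:blue", lw=2, label="LOESS population model")
        ax.set_xlabel("expected log2FC (Bliss sum of singles)")
        ax.set_ylabel("observed log2FC")
        ax.set_title(comparison_id)
        ax.legend(frameon=False, fontsize=8)
        return ax
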