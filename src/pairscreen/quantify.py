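"""From paired FASTQ (or a count table) to per-construct log2 fold changes.

The amplicon is sequenced with a two-forward-read strategy: read 1 reads
through the hU6 expression cassette and read 2 through the sU6 cassette, so
each read carries one spacer at a fixed offset inside a constant vector
context and neither read is reverse-complemented.  A read pair is assigned
to a construct only when both spacers match and the (hU6, sU6) combination
exists in the library; everything else is counted as unassigned.

Screens are run with triplicate infections and a triplicate Cas9-negative
baseline, so each screen timepoint yields the full 3 x 3 = 9 crossed
screen-vs-baseline comparisons per construct.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library import GuideLibrary

__all__ = [
    "Sample", "CountMatrix", "Comparison", "FoldChangeTable",
    "count_reads", "normalize_counts", "make_comparisons", "compute_log2fc",
    "R1_CONTEXT_5P", "R2_CONTEXT_5P", "SPACER_OFFSET",
]

# Constant vector context flanking the spacer in each forward read; the
# spacer starts at SPACER_OFFSET in both reads.
R1_CONTEXT_5P = "TTGTGGAAAGGACGAAACACCG"
R2_CONTEXT_5P = "CTTGTGGAAAGGACGCAACGAG"
CONTEXT_3P = "GTTTAAGAGCTATGCTGG"
SPACER_OFFSET = len(R1_CONTEXT_5P)
assert len(R2_CONTEXT_5P) == SPACER_OFFSET


@dataclass(frozen=True)
class Sample:
    sample_id: str
    role: str  # "baseline" | "screen"
    replicate: int
    timepoint_days: int

    def __post_init__(self):
        if self.role not in ("baseline", "screen"):
            raise ValueError(f"unknown sample role {self.role!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")


@dataclass
class CountMatrix:
    """Integer read counts per construct per sample.

    ``counts`` is a constructs x samples DataFrame of non-negative integers;
    ``unassigned`` holds the per-sample count of read pairs that matched no
    library construct.
    """

    counts: pd.DataFrame
    samples: list[Sample]
    unassigned: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        ids = [s.sample_id for s in self.samples]
        if list(self.counts.columns) != ids:
            raise ValueError("counts columns must match sample ids in order")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id")
        keys = {(s.role, s.replicate, s.timepoint_days) for s in self.samples}
        if len(keys) != len(self.samples):
            raise ValueError("(role, replicate, timepoint) must be unique")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    def sample(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    # -- persistence -------------------------------------------------------
    def to_tsv(self, counts_path, samples_path) -> None:
        out = self.counts.copy()
        out.insert(0, "construct_id", out.index)
        out.to_csv(counts_path, sep="\t", index=False)
        meta = pd.DataFrame(
            [{"sample_id": s.sample_id, "role": s.role,
              "replicate": s.replicate, "timepoint_days": s.timepoint_days,
              "unassigned": self.unassigned.get(s.sample_id, 0)}
             for s in self.samples])
        meta.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path, samples_path) -> "CountMatrix":
        df = pd.read_csv(counts_path, sep="\t")
        df = df.set_index("construct_id")
        meta = pd.read_csv(samples_path, sep="\t")
        samples = [Sample(str(r.sample_id), r.role, int(r.replicate),
                          int(r.timepoint_days))
                   for r in meta.itertuples()]
        unassigned = {}
        if "unassigned" in meta.columns:
            unassigned = dict(zip(meta["sample_id"].astype(str),
                                  meta["unassigned"].astype(int)))
        df = df[[s.sample_id for s in samples]].astype(np.int64)
        return cls(counts=df, samples=samples, unassigned=unassigned)

    @staticmethod
    def concat(parts: list["CountMatrix"]) -> "CountMatrix":
        """Column-bind single-sample matrices sharing a construct index."""
        base = parts[0].counts.index
        for p in parts[1:]:
            if not p.counts.index.equals(base):
                raise ValueError("construct indices differ")
        counts = pd.concat([p.counts for p in parts], axis=1)
        samples = [s for p in parts for s in p.samples]
        unassigned = {k: v for p in parts for k, v in p.unassigned.items()}
        return CountMatrix(counts, samples, unassigned)


@dataclass(frozen=True)
class Comparison:
    screen_sample: str
    baseline_sample: str

    @property
    def comparison_id(self) -> str:
        return f"{self.screen_sample}_vs_{self.baseline_sample}"


class FoldChangeTable:
    """Long table: one row per (construct, comparison).

    Columns: construct_id, comparison_id, observed_log2fc, low_count_flag.
    Low-baseline-count rows are flagged rather than dropped so that the
    scoring stage can report exclusions.
    """

    COLUMNS = ["construct_id", "comparison_id", "observed_log2fc",
               "low_count_flag"]

    def __init__(self, df: pd.DataFrame):
        if list(df.columns) != self.COLUMNS:
            raise ValueError(f"expected columns {self.COLUMNS}")
        if not np.isfinite(df["observed_log2fc"]).all():
            raise ValueError("non-finite log2 fold change")
        dup = df.duplicated(["construct_id", "comparison_id"])
        if dup.any():
            raise ValueError("duplicate (construct, comparison) row")
        self.df = df.reset_index(drop=True)

    def lookup(self) -> pd.DataFrame:
        """Indexed view keyed by (construct_id, comparison_id)."""
        return self.df.set_index(["construct_id", "comparison_id"])

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "FoldChangeTable":
        df = pd.read_csv(path, sep="\t")
        df["low_count_flag"] = df["low_count_flag"].astype(bool)
        return cls(df[cls.COLUMNS])


# ---------------------------------------------------------------------------
# read counting


def _spacer_lookup(lib: GuideLibrary, max_mismatch: int):
    """Build exact (and optional 1-mismatch) spacer -> guide_id maps.

    Returns a function seq -> guide_id or None (None also on ambiguity).
    """
    exact: dict[str, str] = {}
    for g in lib.guides.values():
        if g.spacer in exact and exact[g.spacer] != g.guide_id:
            exact[g.spacer] = None  # ambiguous spacer shared by two guides
        else:
            exact.setdefault(g.spacer, g.guide_id)
    lengths = sorted({len(s) for s in exact}, reverse=True)

    fuzzy: dict[str, str | None] = {}
    if max_mismatch == 1:
        for spacer, gid in exact.items():
            for i, base in enumerate(spacer):
                for alt in "ACGT":
                    if alt == base:
                        continue
                    var = spacer[:i] + alt + spacer[i + 1:]
                    if var in exact:
                        continue  # exact hits take precedence
                    if var in fuzzy and fuzzy[var] != gid:
                        fuzzy[var] = None  # within distance 1 of two spacers
                    else:
                        fuzzy.setdefault(var, gid)

    def match(read: str):
        for L in lengths:
            seq = read[SPACER_OFFSET:SPACER_OFFSET + L]
            hit = exact.get(seq)
            if hit is not None:
                return hit
            if seq in exact:  # present but ambiguous
                return None
        if max_mismatch == 1:
            for L in lengths:
                seq = read[SPACER_OFFSET:SPACER_OFFSET + L]
                if seq in fuzzy:
                    return fuzzy[seq]
        return None

    return match


def count_reads(r1_path, r2_path, lib: GuideLibrary, max_mismatch: int = 0,
                sample: Sample | None = None) -> CountMatrix:
    """Assign paired forward reads to library constructs (one sample).

    A pair increments construct (g_hu6, g_su6) iff read 1 carries g_hu6's
    spacer and read 2 carries g_su6's spacer at the fixed offset (within
    ``max_mismatch``) and that combination exists in the library; otherwise
    it increments the unassigned tally.  Desynchronised files raise.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    if sample is None:
        sample = Sample("sample1", "screen", 1, 28)
    match = _spacer_lookup(lib, max_mismatch)
    combo = {(c.hu6_guide, c.su6_guide): c.construct_id
             for c in lib.constructs.values()}

    order = sorted(lib.constructs)
    counts = dict.fromkeys(order, 0)
    unassigned = 0
    sentinel = object()
    with open(r1_path) as f1, open(r2_path) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        for rec1, rec2 in itertools.zip_longest(it1, it2, fillvalue=sentinel):
            if rec1 is sentinel or rec2 is sentinel:
                raise ValueError(
                    "desynchronized FASTQ files: record counts differ")
            g1 = match(rec1[1])
            g2 = match(rec2[1])
            cid = combo.get((g1, g2)) if g1 and g2 else None
            if cid is None:
                unassigned += 1
            else:
                counts[cid] += 1
    df = pd.DataFrame({sample.sample_id: [counts[c] for c in order]},
                      index=pd.Index(order, name="construct_id"))
    return CountMatrix(df, [sample], {sample.sample_id: unassigned})


# ---------------------------------------------------------------------------
# normalization and fold change


def normalize_counts(cm: CountMatrix, method: str = "median_ratio",
                     pseudocount: float = 1.0) -> pd.DataFrame:
    """Depth-normalize the count matrix (pseudocount is applied later, at
    the log step).

    ``total_count`` scales each column to the mean column total.
    ``median_ratio`` divides each column by the median across constructs of
    count / geometric-row-mean (rows containing any zero are excluded from
    the median), as in DESeq-style size factors.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    X = cm.counts.to_numpy(dtype=float)
    totals = X.sum(axis=0)
    if (totals == 0).any():
        bad = cm.counts.columns[totals == 0].tolist()
        raise ValueError(f"all-zero count column(s): {bad}")
    if method == "total_count":
        factors = totals / totals.mean()
    elif method == "median_ratio":
        pos = (X > 0).all(axis=1)
        if not pos.any():
            raise ValueError("no construct with positive counts in every "
                             "sample; cannot compute median-ratio factors")
        logX = np.log(X[pos])
        geo = np.exp(logX.mean(axis=1, keepdims=True))
        factors = np.median(X[pos] / geo, axis=0)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return pd.DataFrame(X / factors, index=cm.counts.index,
                        columns=cm.counts.columns)


def make_comparisons(samples: list[Sample], timepoint: int) -> list[Comparison]:
    """Cross every screen replicate at ``timepoint`` with every baseline.

    Triplicate screens against a triplicate baseline give the nine
    comparisons per construct used throughout scoring.
    """
    screens = [s for s in samples
               if s.role == "screen" and s.timepoint_days == timepoint]
    baselines = [s for s in samples if s.role == "baseline"]
    if not screens:
        raise ValueError(f"no screen samples at day {timepoint}")
    if not baselines:
        raise ValueError("no baseline samples")
    return [Comparison(s.sample_id, b.sample_id)
            for s in screens for b in baselines]


def compute_log2fc(normalized: pd.DataFrame, cm: CountMatrix,
                   comparisons: list[Comparison],
                   min_baseline_count: int = 30,
                   pseudocount: float = 1.0) -> FoldChangeTable:
    """Per-construct observed log2FC for every comparison.

    observed = log2(normalized screen + pc) - log2(normalized baseline + pc);
    rows whose *raw* baseline count is below ``min_baseline_count`` are
    flagged low_count and excluded downstream.
    """
    frames = []
    for comp in comparisons:
        for sid in (comp.screen_sample, comp.baseline_sample):
            if sid not in normalized.columns:
                raise ValueError(f"unknown sample {sid!r} in comparison "
                                 f"{comp.comparison_id}")
        scr = normalized[comp.screen_sample].to_numpy()
        base = normalized[comp.baseline_sample].to_numpy()
        raw_base = cm.counts[comp.baseline_sample].to_numpy()
        lfc = np.log2(scr + pseudocount) - np.log2(base + pseudocount)
        frames.append(pd.DataFrame({
            "construct_id": normalized.index,
            "comparison_id": comp.comparison_id,
            "observed_log2fc": lfc,
            "low_count_flag": raw_base < min_baseline_count,
        }))
    return FoldChangeTable(pd.concat(frames, ignore_index=True))
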