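"""Read counting, normalization, comparisons, fold changes."""

import numpy as np
import pandas as pd
import pytest

import pairscreen as ps
from pairscreen.quantify import (R1_CONTEXT_5P, R2_CONTEXT_5P, Comparison,
                                 CountMatrix, Sample, compute_log2fc,
                                 count_reads, make_comparisons,
                                 normalize_counts)


def _write_pair(tmp_path, records):
    """records: list of (seq1, seq2)."""
    r1, r2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
    with open(r1, "w") as f1, open(r2, "w") as f2:
        for i, (s1, s2) in enumerate(records):
            f1.write(f"@r{i}/1\n{s1}\n+\n{'I' * len(s1)}\n")
            f2.write(f"@r{i}/2\n{s2}\n+\n{'I' * len(s2)}\n")
    return r1, r2


def _reads_for(lib, construct_id):
    c = lib.constructs[construct_id]
    return (R1_CONTEXT_5P + lib.guide(c.hu6_guide).spacer + "GTTT",
            R2_CONTEXT_5P + lib.guide(c.su6_guide).spacer + "GTTT")


class TestCountReads:
    def test_fastq_round_trip_exact(self, tiny_library, tmp_path):
        """count_reads(simulate_fastq(C)) == C at max_mismatch=0."""
        order = sorted(tiny_library.constructs)
        rng = np.random.default_rng(0)
        col = pd.DataFrame({"s1": rng.integers(0, 30, len(order))},
                           index=pd.Index(order, name="construct_id"))
        cm = CountMatrix(col, [Sample("s1", "screen", 1, 28)], {"s1": 0})
        ps.simulate_fastq(cm, tiny_library, tmp_path / "R1.fastq",
                          tmp_path / "R2.fastq", seed=1)
        got = count_reads(tmp_path / "R1.fastq", tmp_path / "R2.fastq",
                          tiny_library, max_mismatch=0,
                          sample=Sample("s1", "screen", 1, 28))
        pd.testing.assert_frame_equal(got.counts.astype(np.int64),
                                      col.astype(np.int64))
        assert got.unassigned["s1"] == 0

    def test_unknown_combination_unassigned(self, tiny_library, tmp_path):
        """A read pair whose (hU6, sU6) combination is not a library
        construct goes to unassigned, conserving totals."""
        # swap the two reads of a valid paired construct -> combination
        # absent (libraries are single-orientation)
        pc = tiny_library.paired_constructs()[0].construct_id
        s1, s2 = _reads_for(tiny_library, pc)
        r1, r2 = _write_pair(tmp_path, [(s1, s2), (s2, s1)])
        got = count_reads(r1, r2, tiny_library)
        assert got.counts.iloc[:, 0].sum() == 1
        assert got.unassigned[got.samples[0].sample_id] == 1

    def test_empty_fastq(self, tiny_library, tmp_path):
        r1, r2 = _write_pair(tmp_path, [])
        got = count_reads(r1, r2, tiny_library)
        assert got.counts.iloc[:, 0].sum() == 0
        assert got.unassigned[got.samples[0].sample_id] == 0

    def test_desynchronized_files_rejected(self, tiny_library, tmp_path):
        pc = tiny_library.paired_constructs()[0].construct_id
        s1, s2 = _reads_for(tiny_library, pc)
        r1, _ = _write_pair(tmp_path, [(s1, s2), (s1, s2)])
        r2only = tmp_path / "short_r2.fastq"
        r2only.write_text(f"@r0/2\n{s2}\n+\n{'I' * len(s2)}\n")
        with pytest.raises(ValueError, match="desynchronized"):
            count_reads(r1, r2only, tiny_library)

    def test_one_mismatch_recovery_and_ambiguity(self, tiny_library,
                                                 tmp_path):
        pc = tiny_library.paired_constructs()[0].construct_id
        s1, s2 = _reads_for(tiny_library, pc)
        # mutate one base inside the spacer region of read 1
        pos = len(R1_CONTEXT_5P) + 3
        old = s1[pos]
        new = "ACGT"[("ACGT".index(old) + 1) % 4]
        mut = s1[:pos] + new + s1[pos + 1:]
        r1, r2 = _write_pair(tmp_path, [(mut, s2)])
        strict = count_reads(r1, r2, tiny_library, max_mismatch=0)
        assert strict.counts.iloc[:, 0].sum() == 0
        fuzzy = count_reads(r1, r2, tiny_library, max_mismatch=1)
        assert fuzzy.counts.loc[pc].iloc[0] == 1

    def test_conservation_on_simulated_sample(self, tiny_library, tmp_path):
        """assigned + unassigned equals the number of input read pairs."""
        pcs = [c.construct_id for c in tiny_library.paired_constructs()[:3]]
        recs = [_reads_for(tiny_library, p) for p in pcs for _ in range(4)]
        junk = ("A" * len(recs[0][0]), "C" * len(recs[0][1]))
        r1, r2 = _write_pair(tmp_path, recs + [junk] * 5)
        got = count_reads(r1, r2, tiny_library)
        sid = got.samples[0].sample_id
        assert int(got.counts[sid].sum()) + got.unassigned[sid] == 17


class TestNormalization:
    def _cm(self, X, roles=None):
        df = pd.DataFrame(X, columns=[f"s{i+1}" for i in range(X.shape[1])],
                          index=[f"c{i+1}" for i in range(X.shape[0])])
        samples = [Sample(f"s{i+1}", "screen", i + 1, 28)
                   for i in range(X.shape[1])]
        return CountMatrix(df, samples, {})

    def test_identical_columns_unchanged(self):
        cm = self._cm(np.array([[10, 10], [20, 20], [5, 5]]))
        for method in ("median_ratio", "total_count"):
            norm = normalize_counts(cm, method)
            assert np.allclose(norm["s1"], norm["s2"])

    def test_total_count_scale_invariance(self):
        cm = self._cm(np.array([[10, 20], [20, 40], [5, 10]]))
        norm = normalize_counts(cm, "total_count")
        assert np.allclose(norm["s1"], norm["s2"])

    def test_median_ratio_hand_computed(self):
        """3x2 toy matrix against explicit factor arithmetic."""
        X = np.array([[2, 8], [6, 12], [10, 10]], dtype=float)
        cm = self._cm(X.astype(int))
        norm = normalize_counts(cm, "median_ratio")
        geo = np.exp(np.log(X).mean(axis=1, keepdims=True))
        factors = np.median(X / geo, axis=0)  # [1/sqrt(2), sqrt(2)]
        assert factors == pytest.approx([2 ** -0.5, 2 ** 0.5])
        assert np.allclose(norm.to_numpy(), X / factors)

    def test_all_zero_column_rejected(self):
        cm = self._cm(np.array([[0, 5], [0, 4]]))
        with pytest.raises(ValueError, match="all-zero"):
            normalize_counts(cm, "total_count")


class TestComparisons:
    @pytest.mark.parametrize("n_screen,n_base,expected",
                             [(3, 3, 9), (1, 1, 1), (2, 3, 6)])
    def test_cross_product(self, n_screen, n_base, expected):
        samples = [Sample(f"b{i}", "baseline", i + 1, 7)
                   for i in range(n_base)]
        samples += [Sample(f"s{i}", "screen", i + 1, 28)
                    for i in range(n_screen)]
        comps = make_comparisons(samples, 28)
        assert len(comps) == expected
        assert len({c.comparison_id for c in comps}) == expected

    def test_missing_role_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            make_comparisons([Sample("s1", "screen", 1, 28)], 28)
        with pytest.raises(ValueError, match="screen"):
            make_comparisons([Sample("b1", "baseline", 1, 7)], 28)


class TestLog2FC:
    def _setup(self, base, screen, min_baseline_count=0):
        df = pd.DataFrame({"b1": base, "s1": screen},
                          index=[f"c{i}" for i in range(len(base))])
        cm = CountMatrix(df, [Sample("b1", "baseline", 1, 7),
                              Sample("s1", "screen", 1, 28)], {})
        comps = [Comparison("s1", "b1")]
        norm = df.astype(float)  # identity normalization for the oracle
        return compute_log2fc(norm, cm, comps, min_baseline_count,
                              pseudocount=1e-9)

    def test_equal_counts_zero_fc(self):
        fc = self._setup([100, 50], [100, 50])
        assert np.allclose(fc.df["observed_log2fc"], 0.0)

    def test_quarter_depletion_minus_two(self):
        fc = self._setup([400], [100])
        assert fc.df["observed_log2fc"].iloc[0] == pytest.approx(-2.0,
                                                                 abs=1e-6)

    def test_spreadsheet_recomputation(self):
        base, screen = [120, 30, 500, 64], [60, 90, 500, 16]
        fc = self._setup(base, screen)
        expect = np.log2((np.array(screen) + 1e-9)
                         / (np.array(base) + 1e-9))
        assert np.allclose(fc.df["observed_log2fc"], expect)

    def test_low_count_flagging(self):
        fc = self._setup([100, 10], [50, 50], min_baseline_count=30)
        assert list(fc.df["low_count_flag"]) == [False, True]

    def test_antisymmetry_under_role_swap(self):
        """Swapping screen and baseline flips the sign of every log2FC."""
        rng = np.random.default_rng(4)
        a = rng.integers(10, 1000, 20)
        b = rng.integers(10, 1000, 20)
        fwd = self._setup(a, b).df["observed_log2fc"].to_numpy()
        rev = self._setup(b, a).df["observed_log2fc"].to_numpy()
        assert np.allclose(fwd, -rev)
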