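"""Enrichment statistics: windows, fold, permutation null, Fisher, co-occurrence."""

import numpy as np
import pytest
from scipy import stats

from perichrom.enrichment import (
    annotate_features,
    cooccurrence,
    fisher_exact,
    fold_enrichment,
    permutation_test,
    shuffle_peaks,
    subtelomeric_windows,
)
from perichrom.intervals import Genome, GenomicInterval, IntervalSet

from conftest import as_tuples


def iset(genome, triples):
    return IntervalSet(genome, [GenomicInterval(*t) for t in triples])


class TestSubtelomericWindows:
    def test_both_ends(self, kb10_genome):
        w = subtelomeric_windows(kb10_genome, window_bp=1000)
        assert as_tuples(w) == [("chr1", 0, 1000), ("chr1", 9000, 10000)]

    def test_short_chromosome_clips_and_merges(self):
        g = Genome([("chr1", 1500)])
        w = subtelomeric_windows(g, window_bp=1000)
        assert as_tuples(w) == [("chr1", 0, 1500)]

    def test_single_end_modes(self, kb10_genome):
        assert as_tuples(subtelomeric_windows(kb10_genome, 1000, ends="left")) == [
            ("chr1", 0, 1000)
        ]
        assert as_tuples(subtelomeric_windows(kb10_genome, 1000, ends="right")) == [
            ("chr1", 9000, 10000)
        ]

    def test_coverage_identity(self):
        # base coverage equals sum over chromosomes of min(2*window, L)
        g = Genome([("chr1", 3_000_000), ("chr2", 800_000), ("chr3", 200_000)])
        w = subtelomeric_windows(g, window_bp=500_000)
        expect = min(1_000_000, 3_000_000) + min(1_000_000, 800_000) + 200_000
        assert w.total_bases() == expect


class TestFoldEnrichment:
    def test_hand_computed_fold(self, kb10_genome):
        windows = subtelomeric_windows(kb10_genome, window_bp=1000)
        # 6 peaks with midpoints in the windows, 4 outside; all length 100
        starts_in = [100, 300, 500, 9100, 9300, 9500]
        starts_out = [2000, 4000, 6000, 7500]
        peaks = iset(kb10_genome, [("chr1", s, s + 100) for s in starts_in + starts_out])
        res = fold_enrichment(peaks, windows, kb10_genome)
        assert res.f_obs == pytest.approx(0.6)
        assert res.f_exp == pytest.approx(0.2)
        assert res.fold == pytest.approx(3.0)

    def test_uniform_tiling_gives_fold_one(self, kb10_genome):
        windows = subtelomeric_windows(kb10_genome, window_bp=1000)
        peaks = iset(kb10_genome, [("chr1", m - 50, m + 50) for m in range(500, 10_000, 1000)])
        res = fold_enrichment(peaks, windows, kb10_genome)
        assert res.fold == pytest.approx(1.0)

    def test_errors(self, kb10_genome):
        peaks = iset(kb10_genome, [("chr1", 0, 100)])
        with pytest.raises(ValueError, match="regions are empty"):
            fold_enrichment(peaks, iset(kb10_genome, []), kb10_genome)
        windows = subtelomeric_windows(kb10_genome, 1000)
        with pytest.raises(ValueError, match="peaks are empty"):
            fold_enrichment(iset(kb10_genome, []), windows, kb10_genome)

    def test_any_overlap_counts_edge_peaks(self, kb10_genome):
        windows = subtelomeric_windows(kb10_genome, window_bp=1000)
        # midpoint at 1040 (outside) but overlapping the window by 10 bp
        peaks = iset(kb10_genome, [("chr1", 990, 1090)])
        assert fold_enrichment(peaks, windows, kb10_genome, "midpoint").n_obs == 0
        assert fold_enrichment(peaks, windows, kb10_genome, "any_overlap").n_obs == 1


class TestPermutationTest:
    def test_add_one_rule_lower_bound(self, kb10_genome):
        windows = subtelomeric_windows(kb10_genome, 1000)
        peaks = iset(kb10_genome, [("chr1", 5000, 5100)])  # n_obs = 0
        res = permutation_test(peaks, windows, kb10_genome, n_perm=1, seed=0)
        assert res.p_perm == 1.0  # null >= observed is certain at n_obs = 0

    def test_planted_enrichment_detected(self):
        from perichrom.simulate import simulate_genome, simulate_peaks

        g = simulate_genome(4, [1_000_000] * 4)
        for seed in range(3):
            peaks, _ = simulate_peaks(g, 500, 200, subtel_fold=5.0,
                                      window_bp=20_000, seed=seed)
            windows = subtelomeric_windows(g, 20_000)
            res = permutation_test(peaks, windows, g, n_perm=999, seed=seed + 100)
            assert res.p_perm <= 0.01

    def test_reports_binomial_tail(self, kb10_genome):
        windows = subtelomeric_windows(kb10_genome, 1000)
        peaks = iset(kb10_genome, [("chr1", s, s + 10) for s in range(0, 900, 100)])
        res = permutation_test(peaks, windows, kb10_genome, n_perm=9, seed=1)
        expect = stats.binom.sf(res.n_obs - 1, res.n_total, res.f_exp)
        assert res.p_binom == pytest.approx(float(expect))

    def test_same_seed_reproducible(self, kb10_genome):
        windows = subtelomeric_windows(kb10_genome, 1000)
        peaks = iset(kb10_genome, [("chr1", s, s + 50) for s in range(0, 9000, 500)])
        r1 = permutation_test(peaks, windows, kb10_genome, n_perm=99, seed=5)
        r2 = permutation_test(peaks, windows, kb10_genome, n_perm=99, seed=5)
        assert r1 == r2

    def test_genome_wide_placement(self, toy_genome):
        windows = subtelomeric_windows(toy_genome, 100)
        peaks = iset(toy_genome, [("chr1", s, s + 20) for s in range(0, 900, 100)])
        res = permutation_test(peaks, windows, toy_genome, n_perm=99, seed=3,
                               placement="genome_wide")
        assert 0 < res.p_perm <= 1


class TestFisherExact:
    def test_worked_examples(self):
        assert fisher_exact([[3, 1], [1, 3]]) == pytest.approx(34 / 70, abs=1e-12)
        assert fisher_exact([[5, 0], [0, 5]]) == pytest.approx(2 / 252, abs=1e-12)
        assert fisher_exact([[2, 2], [2, 2]]) == pytest.approx(1.0, abs=1e-12)

    def test_one_sided_and_cross_check_with_scipy(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            t = rng.integers(0, 15, size=(2, 2))
            if t.sum() == 0:
                continue
            for alt, scipy_alt in [("two_sided", "two-sided"),
                                   ("greater", "greater"), ("less", "less")]:
                ours = fisher_exact(t, alt)
                ref = stats.fisher_exact(t, alternative=scipy_alt)[1]
                assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_degenerate_tables(self):
        with pytest.raises(ValueError, match="all-zero"):
            fisher_exact([[0, 0], [0, 0]])
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [0, 0]])
        assert fisher_exact([[5, 0], [3, 0]]) == 1.0  # single possible table


class TestShuffleAndAnnotate:
    def test_shuffle_is_length_matched_same_chrom(self, toy_genome):
        peaks = iset(toy_genome, [("chr1", 0, 100), ("chr2", 700, 750)])
        pool = shuffle_peaks(peaks, toy_genome, n_copies=3, seed=0)
        assert len(pool) == 6
        lens = sorted(len(iv) for iv in pool)
        assert lens == [50, 50, 50, 100, 100, 100]
        assert all(iv.chrom == "chr2" for iv in pool if len(iv) == 50)

    def test_saturated_feature(self, kb10_genome):
        peaks = iset(kb10_genome, [("chr1", s, s + 50) for s in range(0, 5000, 500)])
        df = annotate_features(peaks, {"self": peaks}, kb10_genome,
                               n_shuffle=5, seed=0)
        row = df.iloc[0]
        assert row.frac_obs == 1.0
        assert row.fold > 1.0

    def test_empty_track_skipped_with_warning(self, kb10_genome, caplog):
        peaks = iset(kb10_genome, [("chr1", 0, 100)])
        with caplog.at_level("WARNING"):
            df = annotate_features(
                peaks,
                {"empty": iset(kb10_genome, []), "ok": peaks},
                kb10_genome, n_shuffle=2, seed=0,
            )
        assert list(df.feature) == ["ok"]
        assert "skipped" in caplog.text

    def test_flank_expansion_applies_to_point_features(self, kb10_genome):
        peaks = iset(kb10_genome, [("chr1", 4000, 4100)])
        tss = iset(kb10_genome, [("chr1", 3000, 3001)])  # 1 kb upstream of peak
        near = annotate_features(peaks, {"TSS": tss}, kb10_genome,
                                 tss_flank_bp=2000, n_shuffle=2, seed=0)
        far = annotate_features(peaks, {"TSS": tss}, kb10_genome,
                                tss_flank_bp=100, n_shuffle=2, seed=0)
        assert near.iloc[0].n_obs == 1
        assert far.iloc[0].n_obs == 0


class TestCooccurrence:
    def test_whole_genome_marks(self, kb10_genome):
        peaks = iset(kb10_genome, [("chr1", s, s + 50) for s in range(0, 5000, 500)])
        whole = iset(kb10_genome, [("chr1", 0, 10_000)])
        res = cooccurrence(peaks, whole, whole, kb10_genome, seed=0)
        assert res.fraction == 1.0

    def test_disjoint_marks(self, kb10_genome):
        peaks = iset(kb10_genome, [("chr1", 0, 50)])  # inside markA only
        markA = iset(kb10_genome, [("chr1", 0, 100)])
        markB = iset(kb10_genome, [("chr1", 5000, 6000)])
        res = cooccurrence(peaks, markA, markB, kb10_genome, seed=0)
        assert res.n_both == 0

    def test_empty_mark_errors(self, kb10_genome):
        peaks = iset(kb10_genome, [("chr1", 0, 50)])
        with pytest.raises(ValueError, match="mark track is empty"):
            cooccurrence(peaks, iset(kb10_genome, []), peaks, kb10_genome, seed=0)
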