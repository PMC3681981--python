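import numpy as np
import pytest
from scipy import stats

from srnascan import (
    GenomeLayout,
    GenomicInterval,
    TssRecord,
    classify_by_peaks,
    compare_promoter_classes,
    define_promoters,
    ks_two_sample,
)

from conftest import brute_ks_D, make_library


@pytest.fixture
def layout():
    return GenomeLayout.from_pairs([("chr1", 100_000)])


class TestDefinePromoters:
    def test_symmetric_101bp_window(self, layout):
        (w,) = define_promoters([TssRecord("chr1", 1000, "+", "geneA")], layout)
        assert (w.interval.start, w.interval.end) == (949, 1050)
        assert w.interval.length == 101

    def test_strand_does_not_change_window(self, layout):
        (wp,) = define_promoters([TssRecord("chr1", 1000, "+", "a")], layout)
        (wm,) = define_promoters([TssRecord("chr1", 1000, "-", "a")], layout)
        assert wp.interval == wm.interval

    def test_clipping_at_chromosome_start(self):
        layout = GenomeLayout.from_pairs([("chr1", 1000)])
        (w,) = define_promoters([TssRecord("chr1", 30, "-", "g")], layout)
        assert (w.interval.start, w.interval.end) == (0, 80)

    def test_duplicate_positions_collapse_with_gene_ids_joined(self, layout):
        tss = [
            TssRecord("chr1", 1000, "+", "geneA"),
            TssRecord("chr1", 1000, "-", "geneB"),
        ]
        (w,) = define_promoters(tss, layout)
        assert w.gene_ids == ("geneA", "geneB")
        assert w.gene_id == "geneA,geneB"

    def test_tss_beyond_chromosome_raises(self):
        layout = GenomeLayout.from_pairs([("chr1", 500)])
        with pytest.raises(ValueError, match="beyond"):
            define_promoters([TssRecord("chr1", 501, "+", "g")], layout)


class TestClassifyByPeaks:
    def test_one_bp_overlap_is_bound_adjacency_is_not(self, layout):
        (w,) = define_promoters([TssRecord("chr1", 1000, "+", "g")], layout)
        (bound,) = classify_by_peaks([w], [GenomicInterval("chr1", 1049, 1200)])
        assert bound.pcg_bound is True
        (unbound,) = classify_by_peaks([w], [GenomicInterval("chr1", 1050, 1200)])
        assert unbound.pcg_bound is False

    def test_no_peaks_means_all_unbound(self, layout):
        ws = define_promoters(
            [TssRecord("chr1", p, "+", f"g{p}") for p in (1000, 2000)], layout
        )
        assert all(w.pcg_bound is False for w in classify_by_peaks(ws, []))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        layout = GenomeLayout.from_pairs([("chr1", 50_000)])
        tss = [
            TssRecord("chr1", int(p), "+", f"g{i}")
            for i, p in enumerate(
                np.sort(rng.choice(np.arange(100, 49_900), 100, replace=False))
            )
        ]
        windows = define_promoters(tss, layout)
        peaks = []
        for _ in range(20):
            a = int(rng.integers(0, 49_000))
            peaks.append(GenomicInterval("chr1", a, a + int(rng.integers(10, 900))))
        flagged = classify_by_peaks(windows, peaks)
        for w in flagged:
            expected = any(w.interval.overlaps(p) for p in peaks)
            assert w.pcg_bound == expected

    def test_peak_order_independence(self, layout):
        rng = np.random.default_rng(4)
        tss = [TssRecord("chr1", int(p), "+", f"g{p}")
               for p in rng.choice(np.arange(100, 99_000), 50, replace=False)]
        windows = define_promoters(tss, layout)
        peaks = [
            GenomicInterval("chr1", int(a), int(a) + 200)
            for a in rng.integers(0, 98_000, size=15)
        ]
        flags1 = [w.pcg_bound for w in classify_by_peaks(windows, peaks)]
        rng.shuffle(peaks)
        flags2 = [w.pcg_bound for w in classify_by_peaks(windows, peaks)]
        assert flags1 == flags2


class TestKsTwoSample:
    def test_identical_samples(self):
        d, p = ks_two_sample([1.0, 2.0, 2.0, 5.0], [1.0, 2.0, 2.0, 5.0])
        assert d == 0.0
        assert p == 1.0

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([1, 2, 3], [10, 11])
        assert d == 1.0

    def test_hand_enumerated_cdf_steps(self):
        d, _ = ks_two_sample([1.0, 2.0], [1.5])
        assert d == 0.5

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    @pytest.mark.parametrize("seed", range(20))
    def test_D_matches_exhaustive_cdf_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nx = int(rng.integers(1, 9))
        ny = int(rng.integers(1, 10 - nx + 1))
        # small integer support forces ties
        x = rng.integers(0, 5, size=nx).astype(float)
        y = rng.integers(0, 5, size=ny).astype(float)
        d, _ = ks_two_sample(x, y)
        assert d == brute_ks_D(x, y)

    @pytest.mark.parametrize("seed", range(10))
    def test_D_agrees_with_reference_implementation(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30)
        y = rng.normal(0.5, size=40)
        d, _ = ks_two_sample(x, y)
        ref = stats.ks_2samp(x, y, method="asymp")
        assert d == pytest.approx(ref.statistic, abs=1e-12)

    @pytest.mark.parametrize(
        "x,y,d_ref,p_ref",
        [
            # frozen from R ks.test(..., exact=FALSE), the quoted
            # reference implementation of the large-sample p-value
            ([0.1, 0.9, 1.7, 2.2, 3.5], [1.0, 2.1, 2.5, 2.6],
             0.4, 0.86916357240345987),
            (np.arange(0, 2.91, 0.1), np.arange(0.05, 4.0, 0.13),
             0.29032258064516131, 0.15299196206889432),
            (np.array([1, 2, 3, 4, 5, 6, 7, 8]) / 2, [1.2, 3.4, 5.6, 7.8, 9.1],
             0.6, 0.21793961110472471),
        ],
    )
    def test_p_matches_frozen_R_ks_test_values(self, x, y, d_ref, p_ref):
        d, p = ks_two_sample(x, y)
        assert d == pytest.approx(d_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-9)

    def test_invariant_under_strictly_monotone_transform(self):
        rng = np.random.default_rng(8)
        x = rng.exponential(size=25)
        y = rng.exponential(2.0, size=30)
        d1, _ = ks_two_sample(x, y)
        d2, _ = ks_two_sample(np.log1p(x), np.log1p(y))
        assert d1 == pytest.approx(d2, abs=1e-15)

    def test_asymptotic_p_close_to_exact_permutation_p(self):
        """Documented asymptotic-vs-exact gap on a small instance."""
        x = np.array([0.1, 0.9, 1.7])
        y = np.array([1.0, 2.1, 2.5])
        _, p_asymp = ks_two_sample(x, y)
        p_exact = stats.ks_2samp(x, y, method="exact").pvalue
        # small-n asymptotics are conservative but same order of magnitude
        assert 0.2 * p_exact <= p_asymp <= 5 * p_exact


class TestComparePromoterClasses:
    def _promoters(self, layout, positions, bound_flags):
        tss = [TssRecord("chr1", p, "+", f"g{p}") for p in positions]
        windows = define_promoters(tss, layout)
        peaks = [
            w.interval for w, b in zip(windows, bound_flags) if b
        ]
        return classify_by_peaks(windows, peaks)

    def test_counts_split_by_class(self, layout):
        promoters = self._promoters(
            layout, [1_000, 5_000, 9_000, 13_000], [True, True, False, False]
        )
        lib = make_library(
            [("chr1", 980, 1001, 1.0), ("chr1", 8_990, 9_011, 0.5)],
            library_total=1_000.0,
        )
        cmp_ = compare_promoter_classes(lib, promoters)
        assert sorted(cmp_.bound_counts) == [0.0, 1.0 / 1_000.0 * 1e7]
        assert sorted(cmp_.unbound_counts) == [0.0, 0.5 / 1_000.0 * 1e7]
        assert set(cmp_.table.columns) >= {
            "chrom", "start", "end", "gene_ids", "pcg_bound", "raw", "tptm",
        }

    def test_all_promoters_bound_raises(self, layout):
        promoters = self._promoters(layout, [1_000, 5_000], [True, True])
        lib = make_library([("chr1", 980, 1001, 1.0)])
        with pytest.raises(ValueError, match="unbound"):
            compare_promoter_classes(lib, promoters)

    def test_unclassified_promoters_raise(self, layout):
        windows = define_promoters([TssRecord("chr1", 1000, "+", "g")], layout)
        lib = make_library([("chr1", 980, 1001, 1.0)])
        with pytest.raises(ValueError, match="classified"):
            compare_promoter_classes(lib, windows)
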