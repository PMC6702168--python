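import math

import numpy as np
import pandas as pd
import pytest

from actseq.io import GenomicInterval
from actseq.islands import (
    IslandParams,
    call_islands,
    eligible_threshold,
    fdr_filter_vs_control,
    overlap_sets,
    peak_cpm_correlation,
    window_counts,
)


class TestWindowCounts:
    def test_midpoint_rule(self, make_frame):
        frags = make_frame([("chr1", 150, 350, "a")])  # midpoint 250
        counts = window_counts(frags, {"chr1": 1000}, 200)
        assert counts["chr1"].tolist() == [0, 1, 0, 0, 0]

    def test_no_fragments_all_zero(self, make_frame):
        counts = window_counts(make_frame([]), {"chr1": 1000}, 200)
        assert counts["chr1"].sum() == 0

    def test_conservation_and_partial_window(self, make_frame):
        rows = [("chr1", i * 37, i * 37 + 10, "a") for i in range(20)]
        counts = window_counts(make_frame(rows), {"chr1": 700}, 200)
        assert len(counts["chr1"]) == 4  # final partial window kept
        assert counts["chr1"].sum() == 20

    def test_unknown_chromosome_rejected(self, make_frame):
        with pytest.raises(ValueError, match="chrX"):
            window_counts(make_frame([("chrX", 0, 10, "a")]), {"chr1": 100}, 50)


class TestEligibleThreshold:
    def test_poisson_tail_oracle(self):
        # P(X>=2 | 1) = 0.2642 >= 0.2; P(X>=3 | 1) = 0.0803 < 0.2
        assert eligible_threshold(1.0, 0.2) == 3

    def test_vanishing_background(self):
        assert eligible_threshold(1e-9, 0.2) == 1

    def test_non_decreasing_in_lambda(self):
        ks = [eligible_threshold(lam, 0.2) for lam in (0.01, 0.1, 1, 5, 20)]
        assert ks == sorted(ks)


def counts_of(values, chrom="chr1"):
    return {chrom: np.asarray(values, dtype=np.int64)}


class TestCallIslands:
    def params(self, **kw):
        defaults = dict(window_size=200, gap_size=200, eligibility_p=0.2,
                        island_score_threshold=0.0)
        defaults.update(kw)
        return IslandParams(**defaults)

    def test_single_window_score(self):
        islands = call_islands(counts_of([0, 3, 0, 0]), self.params(), lambda_bg=1.0)
        assert len(islands) == 1
        # -ln P(X>=3 | lambda=1) = -ln 0.080301
        assert islands[0].score == pytest.approx(-math.log(0.0803014), abs=1e-4)
        assert islands[0].interval == GenomicInterval("chr1", 200, 400)

    def test_gap_bridges_one_window(self):
        c = counts_of([3, 0, 3, 0, 0, 0])
        islands = call_islands(c, self.params(gap_size=200), lambda_bg=1.0)
        assert len(islands) == 1
        assert islands[0].interval == GenomicInterval("chr1", 0, 600)
        assert islands[0].read_count == 6

    def test_zero_gap_splits(self):
        c = counts_of([3, 0, 3, 0, 0, 0])
        islands = call_islands(c, self.params(gap_size=0), lambda_bg=1.0)
        assert len(islands) == 2

    def test_score_threshold_drops_weak_islands(self):
        c = counts_of([3, 0, 0, 0, 30, 0])
        islands = call_islands(c, self.params(island_score_threshold=10.0),
                               lambda_bg=1.0)
        assert len(islands) == 1 and islands[0].interval.start == 800

    def test_islands_disjoint_sorted_each_contains_eligible_window(self):
        rng = np.random.default_rng(3)
        c = counts_of(rng.poisson(1.0, size=500) + rng.integers(0, 5, size=500))
        params = self.params(gap_size=400)
        k = eligible_threshold(1.5, params.eligibility_p)
        islands = call_islands(c, params, lambda_bg=1.5)
        prev_end = -1
        for isl in islands:
            assert isl.interval.start >= prev_end
            prev_end = isl.interval.end
            w = params.window_size
            member = c["chr1"][isl.interval.start // w: isl.interval.end // w]
            assert (member >= k).any()

    def test_wider_gap_never_increases_island_count(self):
        rng = np.random.default_rng(4)
        c = counts_of(rng.poisson(0.8, size=400) * rng.integers(0, 3, size=400))
        last_n, last_cov = None, None
        for gap in (0, 200, 400, 800):
            islands = call_islands(c, self.params(gap_size=gap), lambda_bg=1.0)
            n = len(islands)
            cov = sum(len(i.interval) for i in islands)
            if last_n is not None:
                assert n <= last_n and cov >= last_cov
            last_n, last_cov = n, cov

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            call_islands(counts_of([1, 2]), self.params(), lambda_bg=0.0)


class TestFdrFilter:
    def islands_for(self, frags, chrom_size=20_000):
        params = IslandParams(island_score_threshold=0.0, gap_size=0)
        counts = window_counts(frags, {"chr1": chrom_size}, 200)
        return call_islands(counts, params)  # background estimated from data

    def test_extreme_enrichment_retained(self, make_frame):
        treat = make_frame([("chr1", 1000, 1100, "a")] * 100
                           + [("chr1", 15_000, 15_100, "a")])
        ctrl = make_frame([("chr1", 18_000, 18_100, "c")] * 50)
        islands = self.islands_for(treat)
        target = [i for i in islands if i.interval.start <= 1050 < i.interval.end]
        retained = fdr_filter_vs_control(islands, treat, ctrl, alpha=0.05)
        assert target and target[0] in retained
        assert all(i.qvalue is not None for i in islands)

    def test_identical_streams_retain_nothing(self, make_frame):
        rng = np.random.default_rng(9)
        rows = [("chr1", int(s), int(s) + 100, "a")
                for s in rng.integers(0, 19_000, size=2000)]
        frags = make_frame(rows)
        islands = self.islands_for(frags)
        assert len(islands) > 10
        retained = fdr_filter_vs_control(islands, frags, frags.copy(), alpha=0.05)
        assert len(retained) <= 0.05 * len(islands)

    def test_alpha_nesting(self, make_frame):
        rng = np.random.default_rng(10)
        treat = make_frame([("chr1", int(s), int(s) + 100, "a")
                            for s in rng.integers(0, 19_000, size=1500)])
        ctrl = make_frame([("chr1", int(s), int(s) + 100, "c")
                           for s in rng.integers(0, 19_000, size=1500)])
        islands = self.islands_for(treat)
        strict = {id(i) for i in fdr_filter_vs_control(islands, treat, ctrl, 0.01)}
        loose = {id(i) for i in fdr_filter_vs_control(islands, treat, ctrl, 0.05)}
        assert strict <= loose

    def test_empty_control_rejected(self, make_frame):
        islands = self.islands_for(make_frame([("chr1", 0, 100, "a")] * 10))
        with pytest.raises(ValueError, match="control"):
            fdr_filter_vs_control(islands, make_frame([("chr1", 0, 100, "a")]),
                                  make_frame([]), 0.05)


class TestOverlapSets:
    def test_one_bp_overlap_counts(self, iv):
        a_only, b_only, a_over, b_over = overlap_sets(
            [iv("chr1", 0, 100)], [iv("chr1", 99, 200)]
        )
        assert not a_only and not b_only
        assert len(a_over) == len(b_over) == 1

    def test_half_open_adjacency_is_not_overlap(self, iv):
        a_only, b_only, a_over, b_over = overlap_sets(
            [iv("chr1", 0, 100)], [iv("chr1", 100, 200)]
        )
        assert len(a_only) == len(b_only) == 1
        assert not a_over and not b_over

    def test_identical_sets(self, iv):
        peaks = [iv("chr1", 0, 100), iv("chr2", 50, 80)]
        a_only, b_only, a_over, b_over = overlap_sets(peaks, list(peaks))
        assert not a_only and not b_only
        assert len(a_over) == len(b_over) == 2


class TestPeakCpmCorrelation:
    def peaks(self, iv, n=3):
        return [iv("chr1", i * 1000, i * 1000 + 500) for i in range(n)]

    def frags_with_counts(self, make_frame, counts, cell="x"):
        rows = []
        for i, c in enumerate(counts):
            rows += [("chr1", i * 1000 + 100 + j, i * 1000 + 200 + j, cell)
                     for j in range(c)]
        return make_frame(rows)

    def test_identical_libraries(self, iv, make_frame):
        frags = self.frags_with_counts(make_frame, [5, 1, 9])
        assert peak_cpm_correlation(frags, frags.copy(), self.peaks(iv)) == 1.0

    def test_rank_formula_oracle(self, iv, make_frame):
        # counts (1,2,3) vs (3,1,2): rho = 1 - 6*(4+1+1)/(3*8) = -0.5
        a = self.frags_with_counts(make_frame, [1, 2, 3])
        b = self.frags_with_counts(make_frame, [3, 1, 2])
        assert peak_cpm_correlation(a, b, self.peaks(iv)) == pytest.approx(-0.5)

    def test_invariant_to_library_scale(self, iv, make_frame):
        a = self.frags_with_counts(make_frame, [1, 2, 3])
        b = self.frags_with_counts(make_frame, [2, 4, 6])
        extra = make_frame([("chr1", 9000, 9100, "x")] * 50)  # off-peak padding
        b_big = pd.concat([b, extra], ignore_index=True)
        assert peak_cpm_correlation(a, b_big, self.peaks(iv)) == pytest.approx(1.0)

    def test_too_few_peaks(self, iv, make_frame):
        a = self.frags_with_counts(make_frame, [1])
        with pytest.raises(ValueError):
            peak_cpm_correlation(a, a, self.peaks(iv, 1))
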