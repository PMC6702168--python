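import numpy as np
import pandas as pd
import pytest

from actseq.metrics import (
    cell_precision,
    cell_sensitivity,
    classify_enhancers,
    expected_sensitivity,
    metrics_summary,
    per_cell_metrics,
    pseudo_bulk,
    tss_profile,
)


class TestTssProfile:
    def test_uniform_fragments_give_flat_profile(self, make_frame):
        rng = np.random.default_rng(1)
        rows = [("chr1", int(s), int(s) + 100, "a")
                for s in rng.integers(0, 999_000, size=40_000)]
        frags = make_frame(rows)
        anchors = [("chr1", int(p), "+") for p in rng.integers(5000, 990_000, 40)]
        prof = tss_profile(frags, anchors, extent=2000, bin_size=200)
        cv = prof.values.std() / prof.values.mean()
        assert cv < 0.25

    def test_anchor_pileup_hits_central_bins(self, make_frame):
        anchors = [("chr1", 10_000, "+"), ("chr1", 50_000, "+")]
        rows = [("chr1", p - 50, p + 50, "a") for p, _, _ in
                [(10_000, 0, 0)] * 5 + [(50_000, 0, 0)] * 5]
        prof = tss_profile(make_frame(rows), anchors, extent=1000, bin_size=100)
        n = len(prof.values)
        central = prof.values[n // 2 - 1: n // 2 + 1]
        assert prof.values.sum() == pytest.approx(central.sum())

    def test_minus_strand_axis_flipped(self, make_frame):
        # one fragment 125 bp downstream of each anchor
        anchors = [("chr1", 10_000, "+"), ("chr1", 50_000, "-")]
        rows = [("chr1", 10_115, 10_135, "a"),   # +125 on the + anchor
                ("chr1", 49_865, 49_885, "a")]   # -125 genomic = +125 downstream
        prof = tss_profile(make_frame(rows), anchors, extent=1000, bin_size=50)
        hits = np.flatnonzero(prof.values)
        assert len(hits) == 1  # both land in the same oriented bin
        assert prof.bin_centers[hits[0]] == pytest.approx(125.0)

    def test_mass_conservation(self, make_frame):
        rng = np.random.default_rng(2)
        rows = [("chr1", int(s), int(s) + 60, "a")
                for s in rng.integers(0, 200_000, size=5000)]
        frags = make_frame(rows)
        anchors = [("chr1", int(p), "-") for p in rng.integers(3000, 195_000, 25)]
        extent, bin_size = 1500, 50
        prof = tss_profile(frags, anchors, extent=extent, bin_size=bin_size)
        mids = (frags["start"] + frags["end"]) // 2
        cooc = sum(
            int(((mids >= p - extent) & (mids < p + extent)).sum())
            for _, p, _ in anchors
        )
        mass = prof.values.sum() * prof.n_anchors * len(frags) / 1e6
        assert mass == pytest.approx(cooc)

    def test_extent_must_be_multiple_of_bin(self, make_frame):
        with pytest.raises(ValueError):
            tss_profile(make_frame([]), [], extent=1000, bin_size=300)


class TestClassifyEnhancers:
    def test_peak_containing_tss_excluded(self, iv):
        peaks = [iv("chr1", 100, 600)]
        enh, prox = classify_enhancers(peaks, [("chr1", 300)], 0)
        assert not enh and prox == peaks

    def test_distal_peak_retained(self, iv):
        peaks = [iv("chr1", 100, 600)]
        enh, prox = classify_enhancers(peaks, [("chr1", 5000)], 1000)
        assert enh == peaks and not prox

    def test_window_extends_exclusion(self, iv):
        peaks = [iv("chr1", 100, 600)]
        assert classify_enhancers(peaks, [("chr1", 1500)], 1000)[0] == []
        assert classify_enhancers(peaks, [("chr1", 1601)], 1000)[0] == peaks

    def test_partition(self, iv):
        rng = np.random.default_rng(5)
        peaks = [iv("chr1", int(s), int(s) + 400)
                 for s in np.arange(0, 100_000, 2000)]
        tss = [("chr1", int(p), "+") for p in rng.integers(0, 100_000, 30)]
        enh, prox = classify_enhancers(peaks, tss, 500)
        assert len(enh) + len(prox) == len(peaks)
        assert set(map(id, enh)).isdisjoint(map(id, prox))


class TestPseudoBulk:
    def test_conservation(self, make_frame):
        rows = [("chr1", i, i + 50, f"c{i % 3}") for i in range(30)]
        agg = pseudo_bulk(make_frame(rows))
        assert len(agg) == 30

    def test_single_cell_identity(self, make_frame):
        df = make_frame([("chr1", 0, 50, "c0"), ("chr1", 5, 55, "c0")])
        pd.testing.assert_frame_equal(pseudo_bulk(df), df)


class TestCellMetrics:
    def test_precision_extremes(self, iv, make_frame):
        peaks = [iv("chr1", 0, 1000)]
        inside = make_frame([("chr1", 100, 300, "a")] * 4)
        outside = make_frame([("chr1", 5000, 5300, "a")] * 4)
        assert cell_precision(inside, peaks) == 1.0
        assert cell_precision(outside, peaks) == 0.0

    def test_precision_requires_fragments(self, iv, make_frame):
        with pytest.raises(ValueError):
            cell_precision(make_frame([]), [iv("chr1", 0, 10)])

    def test_sensitivity_fraction_of_peaks_hit(self, iv, make_frame):
        peaks = [iv("chr1", i * 1000, i * 1000 + 500) for i in range(30)]
        frags = make_frame([("chr1", i * 1000 + 100, i * 1000 + 200, "a")
                            for i in range(3)])
        assert cell_sensitivity(frags, peaks) == pytest.approx(0.1)

    def test_sensitivity_pigeonhole_bound(self, iv, make_frame):
        rng = np.random.default_rng(6)
        peaks = [iv("chr1", i * 1000, i * 1000 + 900) for i in range(50)]
        frags = make_frame([("chr1", int(s), int(s) + 100, "a")
                            for s in rng.integers(0, 49_000, size=12)])
        assert cell_sensitivity(frags, peaks) <= len(frags) / len(peaks)

    def test_sensitivity_monotone_under_added_fragments(self, iv, make_frame):
        peaks = [iv("chr1", i * 1000, i * 1000 + 900) for i in range(20)]
        rows = [("chr1", i * 997, i * 997 + 100, "a") for i in range(15)]
        prev = 0.0
        for k in range(1, 16):
            s = cell_sensitivity(make_frame(rows[:k]), peaks)
            assert s >= prev
            prev = s

    def test_empty_peak_set_rejected(self, make_frame):
        with pytest.raises(ValueError):
            cell_sensitivity(make_frame([("chr1", 0, 10, "a")]), [])

    def test_per_cell_metrics_table(self, iv, make_frame):
        peaks = [iv("chr1", 0, 1000)]
        df = make_frame([("chr1", 100, 200, "a"), ("chr1", 5000, 5100, "a"),
                         ("chr1", 150, 250, "b")])
        cm = per_cell_metrics(df, peaks)
        assert cm.set_index("cell_id").loc["a", "precision"] == 0.5
        assert cm.set_index("cell_id").loc["b", "sensitivity"] == 1.0
        assert (cm["precision"].between(0, 1)).all()

    def test_expected_sensitivity_occupancy_law(self):
        assert expected_sensitivity(0, 100, 0.6) == 0.0
        assert expected_sensitivity(1e9, 100, 0.6) == pytest.approx(1.0)
        # matches direct enumeration at small numbers
        assert expected_sensitivity(10, 5, 1.0) == pytest.approx(1 - 0.8 ** 10)


class TestMetricsSummary:
    def test_quartiles(self):
        cm = pd.DataFrame({"precision": [1, 2, 3, 4, 5], "sensitivity": [0] * 5})
        s = metrics_summary(cm)
        assert s["precision"] == {"min": 1, "q1": 2, "median": 3, "q3": 4, "max": 5}

    def test_single_cell_degenerate(self):
        cm = pd.DataFrame({"precision": [0.4], "sensitivity": [0.1]})
        s = metrics_summary(cm)
        assert len(set(s["precision"].values())) == 1

    def test_permutation_invariant(self):
        rng = np.random.default_rng(7)
        v = rng.random(31)
        a = pd.DataFrame({"precision": v, "sensitivity": v})
        b = pd.DataFrame({"precision": v[::-1], "sensitivity": v[::-1]})
        assert metrics_summary(a) == metrics_summary(b)
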