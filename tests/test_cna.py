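import numpy as np
import pandas as pd
import pytest

from subtype_suite.cna import (Del13qCall, GenomeConfig, classify_del13q,
                               del13q_cohort_stats, gistic_lite, gscore_profile,
                               paired_burden_test, segments_to_markers)
from subtype_suite.synthetic import (Del13qSpec, PeakSpec, default_genome,
                                     make_cna_cohort)

from conftest import make_segment_table


@pytest.fixture
def small_genome():
    return GenomeConfig(chrom_lengths={"1": 50_000_000, "13": 114_000_000},
                        rb1_interval=(47_775_000, 47_954_000))


class TestRasterization:
    def test_marker_count_filter_boundary(self, small_genome):
        segs = make_segment_table([
            ("S1", "1", 0, 10_000_000, 4, 0.8),   # fails n_markers >= 5
            ("S1", "1", 20_000_000, 30_000_000, 5, 0.8),
        ])
        mm = segments_to_markers(segs, small_genome)
        on1 = mm.values[0][: 50]
        assert on1[:10].sum() == 0.0
        assert (on1[20:30] == 0.8).all()

    def test_amplitude_threshold_is_strict(self, small_genome):
        segs = make_segment_table([
            ("S1", "1", 0, 10_000_000, 10, 0.2),    # exactly at threshold: dropped
            ("S1", "1", 20_000_000, 30_000_000, 10, 0.201),
        ])
        mm = segments_to_markers(segs, small_genome)
        assert mm.values[0][:10].sum() == 0.0
        assert mm.values[0][20:30].sum() > 0.0

    def test_amplitude_cap(self, small_genome):
        segs = make_segment_table([("S1", "1", 0, 10_000_000, 10, -3.0)])
        mm = segments_to_markers(segs, small_genome)
        assert mm.values[0][:10].min() == -2.0

    def test_segment_beyond_chromosome_end_rejected(self, small_genome):
        segs = make_segment_table([("S1", "1", 0, 60_000_000, 10, 0.5)])
        with pytest.raises(ValueError, match="beyond"):
            segments_to_markers(segs, small_genome)


class TestGScore:
    def test_worked_example(self, small_genome):
        segs = make_segment_table([
            ("S1", "1", 0, 10_000_000, 10, 0.5),
            ("S2", "1", 0, 10_000_000, 10, 0.5),
            ("S3", "1", 20_000_000, 25_000_000, 10, -0.4),
        ])
        mm = segments_to_markers(segs, small_genome,
                                 sample_ids=["S1", "S2", "S3", "S4"])
        g = gscore_profile(mm)
        assert g["gain"][0] == pytest.approx((0.5 + 0.5) / 4)
        assert g["loss"][20] == pytest.approx(0.4 / 4)

    def test_zero_cohort_and_linearity(self, small_genome):
        segs = make_segment_table([("S1", "1", 0, 10_000_000, 10, 0.5)])
        mm = segments_to_markers(segs, small_genome)
        g1 = gscore_profile(mm)
        mm.values *= 2
        g2 = gscore_profile(mm)
        np.testing.assert_allclose(g2["gain"], 2 * g1["gain"])
        mm.values[:] = 0
        g0 = gscore_profile(mm)
        assert g0["gain"].sum() == 0 and g0["loss"].sum() == 0

    @pytest.mark.parametrize("case", range(10))
    def test_matches_per_marker_loop_oracle(self, case):
        rng = np.random.default_rng(case)
        n, m = int(rng.integers(2, 10)), int(rng.integers(5, 50))
        values = rng.choice([0.0, 0.5, -0.7, 1.2], size=(n, m))
        from subtype_suite.cna import MarkerMatrix
        grid = pd.DataFrame({"chrom": ["1"] * m,
                             "pos": np.arange(m) * 1000 + 500})
        mm = MarkerMatrix(grid, values, [f"S{i}" for i in range(n)])
        g = gscore_profile(mm)
        for marker in range(m):
            gain = sum(max(values[i, marker], 0) for i in range(n)) / n
            loss = sum(max(-values[i, marker], 0) for i in range(n)) / n
            assert g["gain"][marker] == pytest.approx(gain)
            assert g["loss"][marker] == pytest.approx(loss)


class TestGisticLite:
    def test_planted_peak_recovered_without_background(self, small_genome):
        rows = [(f"S{i}", "1", 10_000_000, 15_000_000, 50, 0.5) for i in range(30)]
        rows += [(f"S{i}", "13", 1_000_000, 2_000_000, 50, 0.3)
                 for i in range(30, 100)]
        segs = make_segment_table(rows)
        mm = segments_to_markers(segs, small_genome)
        track = gistic_lite(mm, n_perm=500, seed=0)
        gains = track.peaks[track.peaks["direction"] == "gain"]
        assert any((g["chrom"] == "1") and g["start"] <= 10_500_000 <= g["end"]
                   for _, g in gains.iterrows())

    def test_all_zero_cohort_has_no_peaks(self, small_genome):
        segs = make_segment_table([("S%d" % i, "1", 0, 1_000_000, 10, 0.1)
                                   for i in range(6)])  # all below threshold
        mm = segments_to_markers(segs, small_genome)
        track = gistic_lite(mm, n_perm=100, seed=1)
        assert len(track.peaks) == 0

    def test_sample_order_invariance(self, small_genome):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(8):
            start = int(rng.integers(0, 40)) * 1_000_000
            rows.append((f"S{i}", "1", start, start + 5_000_000, 20,
                         float(rng.choice([0.5, -0.5]))))
        segs = make_segment_table(rows)
        mm = segments_to_markers(segs, small_genome)
        t1 = gistic_lite(mm, sample_subset=[f"S{i}" for i in range(8)],
                         n_perm=100, seed=9)
        t2 = gistic_lite(mm, sample_subset=[f"S{i}" for i in reversed(range(8))],
                         n_perm=100, seed=9)
        np.testing.assert_allclose(t1.g["gain"], t2.g["gain"])

    def test_too_few_samples_or_perms_rejected(self, small_genome):
        segs = make_segment_table([("S1", "1", 0, 5_000_000, 10, 0.5)])
        mm = segments_to_markers(segs, small_genome)
        with pytest.raises(ValueError, match="5 samples"):
            gistic_lite(mm, n_perm=100)
        mm5 = segments_to_markers(segs, small_genome,
                                  sample_ids=[f"S{i}" for i in range(5)])
        with pytest.raises(ValueError, match="n_perm"):
            gistic_lite(mm5, n_perm=5)


class TestDel13qClassifier:
    RB1 = (47_775_000, 47_954_000)
    LDB = 54_700_000

    def geometry_cases(self):
        """(loss interval or None, expected status, expected ldb) grid."""
        rb1_s, rb1_e = self.RB1
        return [
            (None, "none", False),
            ((48_500_000, 50_000_000), "typeI", False),         # distal of RB1
            ((40_000_000, rb1_s), "typeI", False),              # ends at RB1 start: no overlap (half-open)
            ((rb1_s - 1_000_000, rb1_s + 1), "typeII", False),  # 1 bp overlap
            ((rb1_s - 1_000_000, rb1_e + 1_000_000), "typeII", False),  # spanning
            ((rb1_s + 10_000, rb1_e - 10_000), "typeII", False),        # contained
            ((rb1_e, rb1_e + 2_000_000), "typeI", False),       # starts at RB1 end
            ((50_000_000, self.LDB), "typeI", False),           # ends at boundary
            ((50_000_000, self.LDB + 1), "typeI", True),        # 1 bp past boundary
            ((rb1_s - 500_000, self.LDB + 1), "typeII", True),
        ]

    def test_exhaustive_geometry_grid(self, small_genome):
        for interval, status, ldb in self.geometry_cases():
            rows = [] if interval is None else [
                ("S1", "13", interval[0], interval[1], 50, -0.5)]
            segs = (make_segment_table(rows).for_sample("S1") if rows
                    else pd.DataFrame(columns=["sample", "chrom", "start", "end",
                                               "n_markers", "seg_mean"]))
            call = classify_del13q(segs, small_genome, sample_id="S1")
            assert call.status == status, (interval, call.status)
            assert call.ldb == ldb, (interval, call.ldb)

    def test_segment_filters_gate_the_call(self, small_genome):
        # loss at exactly -0.2 or with 4 markers does not qualify
        for n_markers, amp in ((50, -0.2), (4, -0.5)):
            segs = make_segment_table([("S1", "13", 48_500_000, 50_000_000,
                                        n_markers, amp)]).for_sample("S1")
            call = classify_del13q(segs, small_genome, sample_id="S1")
            assert call.status == "none"
        segs = make_segment_table([("S1", "13", 48_500_000, 50_000_000, 5,
                                    -0.201)]).for_sample("S1")
        assert classify_del13q(segs, small_genome).status == "typeI"

    def test_biallelic_from_deep_amplitude(self, small_genome):
        segs = make_segment_table([("S1", "13", 48_500_000, 50_000_000, 50,
                                    -0.9)]).for_sample("S1")
        assert classify_del13q(segs, small_genome).biallelic
        segs = make_segment_table([("S1", "13", 48_500_000, 50_000_000, 50,
                                    -0.89)]).for_sample("S1")
        assert not classify_del13q(segs, small_genome).biallelic

    def test_flags_require_deletion(self):
        with pytest.raises(ValueError):
            Del13qCall("S1", "none", ldb=True, biallelic=False,
                       distal_boundary=None)

    def test_missing_annotation_rejected(self):
        genome = GenomeConfig(chrom_lengths={"13": 114_000_000})
        segs = make_segment_table([("S1", "13", 1_000_000, 9_000_000, 50,
                                    -0.5)]).for_sample("S1")
        with pytest.raises(ValueError, match="RB1"):
            classify_del13q(segs, genome)

    def test_planted_cohort_recovery(self, genome):
        labels = np.ones(60, dtype=int)
        segs, truth = make_cna_cohort(labels, [], genome,
                                      Del13qSpec(rate=0.7, type2_fraction=1.0),
                                      background_rate=0.0, seed=21)
        from subtype_suite.cna import classify_del13q_cohort
        calls = {c.sample_id: c for c in classify_del13q_cohort(segs, genome)}
        for sid, t in truth.del13q.items():
            got = calls.get(sid, Del13qCall(sid, "none", False, False, None))
            assert got.status == t["status"]
            if t["status"] != "none":
                assert got.ldb == t["ldb"] and got.biallelic == t["biallelic"]


class TestCohortStats:
    def _calls(self, rng, n, type2_prob):
        calls, labels = [], {}
        for i in range(n):
            sid = f"S{i}"
            group = "A" if i < n // 2 else "B"
            labels[sid] = group
            prob = type2_prob[group]
            status = "typeII" if rng.random() < prob else "typeI"
            ldb = rng.random() < (0.6 if status == "typeII" else 0.1)
            calls.append(Del13qCall(sid, status, ldb, False, 50_000_000))
        return calls, labels

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(0)
        calls, labels = self._calls(rng, 200, {"A": 0.8, "B": 0.2})
        report = del13q_cohort_stats(calls, labels, {"A"}, {"B"})
        assert report["type2_by_supergroup"]["test"].p_value < 0.05
        assert report["ldb_type2_cooccurrence"]["test"] is not None

    def test_balanced_split_not_significant_on_average(self):
        pvals = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            calls, labels = self._calls(rng, 60, {"A": 0.5, "B": 0.5})
            report = del13q_cohort_stats(calls, labels, {"A"}, {"B"})
            test = report["type2_by_supergroup"]["test"]
            if test is not None:
                pvals.append(test.p_value)
        assert np.mean([p < 0.05 for p in pvals]) <= 0.2

    def test_zero_margin_reported_na(self):
        calls = [Del13qCall("S1", "typeII", False, False, 1),
                 Del13qCall("S2", "typeII", False, False, 1)]
        labels = {"S1": "A", "S2": "B"}
        report = del13q_cohort_stats(calls, labels, {"A"}, {"B"})
        assert report["type2_by_supergroup"]["test"] is None


class TestPairedBurden:
    def test_worked_example(self, small_genome):
        def seg_rows(sample, count, offset=0):
            return [(sample, "1", (offset + j) * 2_000_000,
                     (offset + j) * 2_000_000 + 1_000_000, 10, 0.5)
                    for j in range(count)]

        pre = make_segment_table(seg_rows("P1", 1) + seg_rows("P2", 1)
                                 + seg_rows("P3", 2))
        post = make_segment_table(seg_rows("P1", 3) + seg_rows("P2", 4)
                                  + seg_rows("P3", 5))
        out = paired_burden_test(pre, post, small_genome)
        assert out["test"].p_value == pytest.approx(0.25)
        assert out["mean_pre"] == pytest.approx(4 / 3)
        assert out["mean_post"] == pytest.approx(4.0)

    def test_identical_timepoints_surface_no_change(self, small_genome):
        rows = [("P1", "1", 0, 1_000_000, 10, 0.5)]
        pre = make_segment_table(rows)
        post = make_segment_table(rows)
        out = paired_burden_test(pre, post, small_genome)
        assert out["test"].method == "wilcoxon-signed-rank (no change)"
        assert out["test"].p_value == 1.0

    def test_unpaired_sample_named(self, small_genome):
        pre = make_segment_table([("P1", "1", 0, 1_000_000, 10, 0.5)])
        post = make_segment_table([("P2", "1", 0, 1_000_000, 10, 0.5)])
        with pytest.raises(ValueError, match="P1"):
            paired_burden_test(pre, post, small_genome)
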