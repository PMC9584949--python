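"""Copy-number workflow: bait filtering, logR, GC correction,
segmentation (vs a brute-force oracle), cell fractions and filters."""

import itertools

import numpy as np
import pandas as pd
import pytest

from clonaldyn.cna import (
    BaitInterval,
    LogRTrack,
    Segment,
    _optimal_partition,
    call_cna,
    cell_fraction_from_logr,
    compute_logr,
    default_penalty,
    gc_correct,
    make_bins,
    offtarget_bins,
    run_cna,
    segment_logr,
)
from clonaldyn.synthetic import GenomeFixtureSpec, PlantedCNA, gen_cna_readset, random_baits


def _bins_1kb(n=10, chrom="1", counts=None):
    df = make_bins({chrom: n * 1000}, 1000)
    df["count"] = counts if counts is not None else 5
    return df


class TestOfftargetBins:
    def test_no_baits_is_plain_aggregation(self):
        fine = _bins_1kb(2000, counts=3)
        out = offtarget_bins(fine, [], out_width=1_000_000)
        assert len(out) == 2
        assert (out["count"] == 3000).all()
        assert not out["masked"].any()

    def test_one_bp_overlap_drops_both_bins(self):
        fine = _bins_1kb(10, counts=1)
        out = offtarget_bins(fine, [BaitInterval("1", 1500, 2500)], out_width=10_000)
        # bait [1500, 2500) touches 1 kb bins [1000,2000) and [2000,3000)
        assert out["count"].iloc[0] == 8
        assert out["width_bp"].iloc[0] == 8000

    def test_saturated_chromosome_masked(self):
        fine = _bins_1kb(10, counts=1)
        out = offtarget_bins(fine, [BaitInterval("1", 0, 10_000)], out_width=10_000)
        assert out["masked"].all()

    def test_unknown_chromosome_warns(self):
        fine = _bins_1kb(10)
        with pytest.warns(UserWarning, match="unknown"):
            offtarget_bins(fine, [BaitInterval("chrZ", 0, 100)], out_width=10_000)

    def test_half_surviving_rule(self):
        fine = _bins_1kb(10, counts=1)
        out = offtarget_bins(fine, [BaitInterval("1", 0, 5500)], out_width=10_000)
        # 6 of 10 kb removed -> below the 50% surviving threshold
        assert bool(out["masked"].iloc[0])


def test_bin_reads_from_sam(tmp_path):
    from clonaldyn.cna import bin_reads

    sam = tmp_path / "reads.sam"
    sam.write_text(
        "@HD\tVN:1.6\tSO:coordinate\n"
        "@SQ\tSN:1\tLN:10000\n"
        "r1\t0\t1\t150\t60\t50M\t*\t0\t0\t*\t*\n"
        "r2\t0\t1\t950\t60\t50M\t*\t0\t0\t*\t*\n"
        "r3\t0\t1\t2500\t60\t50M\t*\t0\t0\t*\t*\n"
        "r4\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n"  # unmapped: skipped
    )
    bins = bin_reads(str(sam), {"1": 10_000}, width=1000)
    assert bins["count"].tolist()[:3] == [2, 0, 1]
    assert bins["count"].sum() == 3


def _frame(counts, chrom="1", width=1_000_000):
    df = make_bins({chrom: len(counts) * width}, width)
    df["count"] = counts
    return df


class TestComputeLogr:
    def test_identity_gives_zero(self):
        s = _frame(np.full(50, 100))
        track = compute_logr(s, s.copy())
        assert np.allclose(track.unmasked["logr"], 0.0)

    def test_global_depth_invariance(self):
        rng = np.random.default_rng(0)
        c = _frame(rng.poisson(200, 80))
        s = _frame(rng.poisson(300, 80))
        t1 = compute_logr(s, c)
        s2, c2 = s.copy(), c.copy()
        s2["count"] *= 5
        c2["count"] *= 3
        t2 = compute_logr(s2, c2)
        assert np.allclose(t1.unmasked["logr"], t2.unmasked["logr"], atol=1e-12)

    def test_zero_control_masked_not_pseudocounted(self):
        c = _frame(np.array([100, 0, 100, 100]))
        s = _frame(np.array([100, 50, 100, 100]))
        track = compute_logr(s, c)
        assert bool(track.bins["masked"].iloc[1])
        assert track.bins["logr"].iloc[1] != track.bins["logr"].iloc[1]  # NaN

    def test_planted_loss_regional_mean(self):
        # event small relative to the genome, so the mean-ratio
        # normalization is essentially untouched by it
        rng = np.random.default_rng(1)
        n = 2000
        c = _frame(rng.poisson(5000, n))
        mu = np.full(n, 5000.0)
        mu[50:80] *= 0.85  # single-copy loss in 30% of cells
        s = _frame(rng.poisson(mu))
        track = compute_logr(s, c)
        region = track.bins["logr"].to_numpy()[50:80]
        assert abs(region.mean() - np.log2(0.85)) < 0.02

    def test_sex_chromosomes_excluded_from_normalization(self):
        a = make_bins({"1": 3_000_000, "X": 3_000_000}, 1_000_000)
        c = a.copy()
        c["count"] = 100
        s = a.copy()
        s["count"] = np.where(s["chrom"] == "X", 50, 100)  # male-like X
        track = compute_logr(s, c)
        auto = track.bins[track.bins["chrom"] == "1"]["logr"]
        assert np.allclose(auto, 0.0)

    def test_mismatched_frames_rejected(self):
        s = _frame(np.full(10, 5))
        c = _frame(np.full(12, 5))
        with pytest.raises(ValueError, match="differ"):
            compute_logr(s, c)


class TestGcCorrect:
    def _track(self, logr, gc):
        df = make_bins({"1": len(logr) * 1_000_000}, 1_000_000)
        df["gc"] = gc
        df["logr"] = logr
        df["masked"] = False
        return LogRTrack(df)

    def test_missing_gc_is_noop(self):
        df = make_bins({"1": 5_000_000}, 1_000_000)
        df["logr"] = 0.1
        df["masked"] = False
        with pytest.warns(UserWarning, match="no gc"):
            out = gc_correct(LogRTrack(df))
        assert np.allclose(out.bins["logr"], 0.1)

    def test_degenerate_gc_is_noop(self):
        track = self._track(np.zeros(30), np.full(30, 0.4))
        with pytest.warns(UserWarning, match="degenerate"):
            gc_correct(track)

    def test_gc_independent_track_unchanged(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 0.05, 300)
        gc = rng.uniform(0.35, 0.55, 300)
        out = gc_correct(self._track(y, gc))
        assert np.abs(out.bins["logr"].to_numpy() - y).max() < 0.06

    def test_planted_wave_removed(self):
        # logr that is a pure function of gc: residual SD shrinks >= 5x
        rng = np.random.default_rng(3)
        gc = rng.uniform(0.35, 0.55, 400)
        y = 2.0 * (gc - 0.45) + rng.normal(0, 0.01, 400)
        out = gc_correct(self._track(y, gc))
        assert y.std() / out.bins["logr"].std() >= 5

    def test_cna_step_survives_correction(self):
        spec = GenomeFixtureSpec(
            events=(PlantedCNA("1", 40_000_000, 70_000_000, "loss", 0.30),),
            gc_wave_amplitude=0.1, seed=5,
        )
        s, c, _ = gen_cna_readset(spec)
        track = gc_correct(compute_logr(s, c))
        y = track.bins[track.bins["chrom"] == "1"]["logr"].to_numpy()
        assert abs(y[40:70].mean() - np.log2(0.85)) < 0.03
        assert abs(y[80:].mean()) < 0.02


def brute_force_partition(y, penalty, max_segments=4):
    """Exhaustive search over all partitions with up to max_segments."""
    n = len(y)
    best, best_cost = [0], np.inf
    for k in range(max_segments):
        for cuts in itertools.combinations(range(1, n), k):
            bps = [0, *cuts, n]
            cost = sum(
                ((y[a:b] - y[a:b].mean()) ** 2).sum() + penalty
                for a, b in zip(bps[:-1], bps[1:])
            )
            if cost < best_cost:
                best, best_cost = list(bps[:-1]), cost
    return best


class TestSegmentLogr:
    def test_dp_matches_brute_force(self):
        rng = np.random.default_rng(4)
        y = np.concatenate([np.zeros(8), -0.5 * np.ones(6), 0.2 * np.ones(8)])
        y += rng.normal(0, 0.05, len(y))
        pen = default_penalty(y)
        assert _optimal_partition(y, pen) == brute_force_partition(y, pen)

    def test_flat_track_single_segment(self):
        df = make_bins({"1": 60_000_000, "2": 40_000_000}, 1_000_000)
        rng = np.random.default_rng(5)
        df["logr"] = rng.normal(0, 0.03, len(df))
        df["masked"] = False
        segs = segment_logr(LogRTrack(df))
        assert [s.chrom for s in segs] == ["1", "2"]

    def test_single_step_localized(self):
        df = make_bins({"1": 150_000_000}, 1_000_000)
        rng = np.random.default_rng(6)
        y = np.zeros(150)
        y[60:90] = -0.234
        df["logr"] = y + rng.normal(0, 0.05, 150)
        df["masked"] = False
        segs = segment_logr(LogRTrack(df))
        assert len(segs) == 3
        assert abs(segs[1].start - 60_000_000) <= 1_000_000
        assert abs(segs[1].end - 90_000_000) <= 1_000_000

    def test_adjacent_opposite_steps(self):
        df = make_bins({"1": 120_000_000}, 1_000_000)
        rng = np.random.default_rng(7)
        y = np.zeros(120)
        y[30:60] = -0.3
        y[60:90] = 0.3
        df["logr"] = y + rng.normal(0, 0.05, 120)
        df["masked"] = False
        segs = segment_logr(LogRTrack(df))
        assert len(segs) == 4

    def test_fully_masked_chromosome_flagged(self):
        df = make_bins({"1": 5_000_000}, 1_000_000)
        df["logr"] = np.nan
        df["masked"] = True
        with pytest.warns(UserWarning, match="unmasked"):
            segs = segment_logr(LogRTrack(df))
        assert segs == []


class TestCellFraction:
    def test_zero_logr(self):
        assert cell_fraction_from_logr(0.0, "loss") == 0.0
        assert cell_fraction_from_logr(0.0, "gain") == 0.0

    def test_inversion_examples(self):
        assert cell_fraction_from_logr(np.log2(0.95), "loss") == pytest.approx(0.10)
        assert cell_fraction_from_logr(np.log2(1.15), "gain") == pytest.approx(0.30)

    def test_inconsistent_sign_gives_zero(self):
        assert cell_fraction_from_logr(0.1, "loss") == 0.0
        assert cell_fraction_from_logr(-0.1, "gain") == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cell_fraction_from_logr(np.nan, "loss")
        with pytest.raises(ValueError):
            cell_fraction_from_logr(0.0, "deletion")


class TestCallCna:
    def _seg(self, mean_logr, length_mb):
        return Segment("1", 0, int(length_mb * 1e6), int(length_mb), mean_logr)

    def test_large_strong_loss_retained(self):
        calls = call_cna([self._seg(np.log2(0.85), 30)])
        assert bool(calls["retained"].iloc[0])
        assert calls["call"].iloc[0] == "loss"
        assert calls["cell_fraction"].iloc[0] == pytest.approx(0.30)

    def test_short_event_filtered_by_length(self):
        calls = call_cna([self._seg(np.log2(0.85), 15)])
        assert not calls["retained"].iloc[0]
        assert calls["filter_reason"].iloc[0] == "length"

    def test_weak_event_filtered_by_fraction(self):
        calls = call_cna([self._seg(np.log2(1 - 0.05 / 2), 30)])
        assert not calls["retained"].iloc[0]
        assert "cell_fraction" in calls["filter_reason"].iloc[0]


class TestEndToEnd:
    EVENTS = (
        PlantedCNA("1", 40_000_000, 70_000_000, "loss", 0.30),
        PlantedCNA("2", 10_000_000, 45_000_000, "gain", 0.30),
    )

    def test_wgs_recovery_single_replicate(self):
        s, c, truth = gen_cna_readset(GenomeFixtureSpec(events=self.EVENTS, seed=0))
        _, calls = run_cna(s, c)
        ret = calls[calls["retained"]]
        assert len(ret) == 2
        for _, ev in truth.iterrows():
            m = ret[(ret["chrom"] == ev["chrom"]) & (ret["call"] == ev["direction"])]
            assert len(m) == 1
            assert abs(m["cell_fraction"].iloc[0] - ev["cell_fraction"]) <= 0.05

    def test_targeted_and_wgs_paths_concordant(self):
        baits = random_baits({"1": 150_000_000, "2": 120_000_000, "3": 90_000_000,
                              "X": 60_000_000}, n_per_chrom=400, seed=1)
        st, ct, _ = gen_cna_readset(
            GenomeFixtureSpec(events=self.EVENTS, bin_width=1000, depth_per_bin=2.0, seed=7)
        )
        _, calls_t = run_cna(st, ct, baits=baits, mode="targeted")
        sw, cw, _ = gen_cna_readset(
            GenomeFixtureSpec(events=self.EVENTS, bin_width=100_000, depth_per_bin=1200.0, seed=8)
        )
        _, calls_w = run_cna(sw, cw)
        rt = calls_t[calls_t["retained"]].reset_index(drop=True)
        rw = calls_w[calls_w["retained"]].reset_index(drop=True)
        assert list(rt["chrom"]) == list(rw["chrom"])
        assert list(rt["call"]) == list(rw["call"])
        # boundaries agree within one coarse (1 Mb) bin
        assert (np.abs(rt["start"].to_numpy() - rw["start"].to_numpy()) <= 1_000_000).all()
        assert (np.abs(rt["end"].to_numpy() - rw["end"].to_numpy()) <= 1_000_000).all()

    def test_targeted_mode_requires_baits(self):
        s, c, _ = gen_cna_readset(GenomeFixtureSpec(seed=0))
        with pytest.raises(ValueError, match="bait"):
            run_cna(s, c, mode="targeted")
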