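"""Gridded-biopsy estimators: merging, coverage, burden, density,
consequence ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonaldyn.clone_genomics import (
    MutationCall,
    clone_area_bounds,
    clone_density,
    gene_tissue_fraction,
    merge_clones,
    mutation_burden,
    rank_tp53_consequence,
    shared_mutation_decay,
)
from clonaldyn.clone_genomics import GenePanel

from conftest import make_sample

MUT_A = ("1", 100, "C", "T", 0.2)
MUT_B = ("2", 900, "G", "A", 0.1)


class TestSharedMutationDecay:
    def test_disjoint_samples_share_nothing(self):
        s1 = make_sample("a", 0, 0, [MUT_A])
        s2 = make_sample("b", 0, 1, [MUT_B])
        df = shared_mutation_decay([s1, s2])
        assert df["mean_shared"].tolist() == [0.0]
        assert df["distance_mm"].tolist() == [2.0]

    def test_planted_block_clone_decay(self):
        # one clone across a 2x2 block in a 3x3 grid: sharing at 2 mm and
        # 2.83 mm only (brute-force pair enumeration fixes the expectation)
        samples = []
        for r in range(3):
            for c in range(3):
                muts = [MUT_A] if (r < 2 and c < 2) else []
                samples.append(make_sample(f"s{r}{c}", r, c, muts))
        df = shared_mutation_decay(samples)
        near = df[df["distance_mm"] < 3.0]
        far = df[df["distance_mm"] > 3.0]
        assert set(np.round(near["distance_mm"], 2)) == {2.0, 2.83}
        assert (near["mean_shared"] > 0).all()
        assert (far["mean_shared"] == 0).all()

    def test_ubiquitous_mutation(self):
        samples = [make_sample(f"s{r}{c}", r, c, [MUT_A]) for r in range(2) for c in range(3)]
        df = shared_mutation_decay(samples)
        assert (df["mean_shared"] == 1.0).all()

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            shared_mutation_decay([make_sample("a", 0, 0, [MUT_A])])


class TestMergeClones:
    def test_private_mutation_single_event(self):
        events = merge_clones([make_sample("a", 0, 0, [MUT_A]), make_sample("b", 3, 3, [])])
        assert len(events) == 1
        assert events[0].aggregated_vaf == pytest.approx(0.2)

    def test_edge_and_diagonal_neighbours_merge(self):
        # 2 mm and 2.83 mm are both < 3 mm
        for pos in [(0, 1), (1, 1)]:
            events = merge_clones(
                [make_sample("a", 0, 0, [MUT_A]), make_sample("b", *pos, [MUT_A])]
            )
            assert len(events) == 1, pos

    def test_distant_samples_stay_separate(self):
        events = merge_clones(
            [make_sample("a", 0, 0, [MUT_A]), make_sample("b", 0, 2, [MUT_A])]
        )
        assert len(events) == 2  # 4 mm >= 3 mm

    def test_chain_merging_is_transitive(self):
        # a-b adjacent, b-c adjacent, a-c distant: one event spans all three
        samples = [make_sample(s, 0, i, [MUT_A]) for i, s in enumerate("abc")]
        events = merge_clones(samples)
        assert len(events) == 1
        assert events[0].sample_ids == ("a", "b", "c")

    def test_aggregated_vaf_is_area_weighted(self):
        s1 = make_sample("a", 0, 0, [("1", 100, "C", "T", 0.4)], area=2.0)
        s2 = make_sample("b", 0, 1, [("1", 100, "C", "T", 0.1)], area=4.0)
        (event,) = merge_clones([s1, s2])
        assert event.aggregated_vaf == pytest.approx((0.4 * 2 + 0.1 * 4) / 6)
        assert event.area_lower == pytest.approx(0.4 * 2 + 0.1 * 4)
        assert event.area_lower <= event.area_upper

    def test_order_invariance_and_idempotence(self):
        samples = [
            make_sample("a", 0, 0, [MUT_A, MUT_B]),
            make_sample("b", 0, 1, [MUT_A]),
            make_sample("c", 2, 2, [MUT_A]),
        ]
        ev1 = merge_clones(samples)
        ev2 = merge_clones(samples[::-1])
        key = lambda e: (e.key, e.sample_ids)
        assert sorted(map(key, ev1)) == sorted(map(key, ev2))

    def test_duplicate_rows_rejected(self):
        s = make_sample("a", 0, 0, [MUT_A, MUT_A])
        with pytest.raises(ValueError, match="duplicate"):
            merge_clones([s])

    @given(threshold=st.floats(min_value=0.5, max_value=12.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_event_count_monotone_in_threshold(self, threshold):
        samples = [
            make_sample("a", 0, 0, [MUT_A]),
            make_sample("b", 0, 2, [MUT_A]),
            make_sample("c", 3, 3, [MUT_A]),
            make_sample("d", 0, 1, [MUT_A]),
        ]
        n_at = len(merge_clones(samples, threshold=threshold))
        n_wider = len(merge_clones(samples, threshold=threshold + 2.0))
        assert n_wider <= n_at


class TestCloneAreaBounds:
    @pytest.mark.parametrize(
        "vaf,area,lower,upper",
        [(0.0, 2.0, 0.0, 0.0), (0.25, 2.0, 0.5, 1.0), (0.6, 2.0, 1.2, 2.0)],
    )
    def test_worked_examples(self, vaf, area, lower, upper):
        assert clone_area_bounds(vaf, area) == (pytest.approx(lower), pytest.approx(upper))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            clone_area_bounds(1.2, 2.0)
        with pytest.raises(ValueError):
            clone_area_bounds(0.2, 0.0)

    @given(vaf=st.floats(0.0, 1.0), area=st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_lower_below_upper_and_linear_in_area(self, vaf, area):
        lo, hi = clone_area_bounds(vaf, area)
        assert lo <= hi + 1e-12
        lo2, hi2 = clone_area_bounds(vaf, 2 * area)
        assert lo2 == pytest.approx(2 * lo) and hi2 == pytest.approx(2 * hi)


class TestGeneTissueFraction:
    def test_absent_gene_is_zero_with_warning(self):
        samples = [make_sample("a", 0, 0, [MUT_A])]
        with pytest.warns(UserWarning):
            lo, hi = gene_tissue_fraction(samples, "NOPE")
        assert lo == 0.0 and hi == 0.0

    def test_single_mutation_among_four_biopsies(self):
        samples = [make_sample("a", 0, 0, [("1", 1, "C", "T", 0.5, "Trp53")])]
        samples += [make_sample(s, 0, i + 1, []) for i, s in enumerate("bcd")]
        lo, hi = gene_tissue_fraction(samples, "Trp53")
        assert lo == pytest.approx(0.125)  # (0.5+0+0+0)/4
        assert hi == pytest.approx(0.25)

    def test_per_biopsy_cap(self):
        muts = [("1", i, "C", "T", 0.5, "Trp53") for i in range(3)]
        lo, hi = gene_tissue_fraction([make_sample("a", 0, 0, muts)], "Trp53")
        assert lo == 1.0 and hi == 1.0

    def test_synonymous_excluded(self):
        muts = [("1", 1, "C", "T", 0.4, "Trp53", "synonymous")]
        with pytest.warns(UserWarning):
            lo, _ = gene_tissue_fraction([make_sample("a", 0, 0, muts)], "Trp53")
        assert lo == 0.0


class TestMutationBurden:
    PANEL = GenePanel(genes=("G",), synonymous_footprint=100_000)

    def test_no_synonymous_calls(self):
        with pytest.warns(UserWarning, match="synonymous"):
            df = mutation_burden([make_sample("a", 0, 0, [MUT_A])], self.PANEL)
        assert df["burden_per_mb"].iloc[0] == 0.0

    def test_single_het_mutation(self):
        muts = [("1", 1, "C", "T", 0.5, "G", "synonymous")]
        df = mutation_burden([make_sample("a", 0, 0, muts)], self.PANEL)
        # min(2*0.5, 1) / 1e5 * 1e6 = 10 per Mb
        assert df["burden_per_mb"].iloc[0] == pytest.approx(10.0)
        assert df.attrs["tissue_mean"] == pytest.approx(10.0)

    def test_vaf_only_variant_halves(self):
        muts = [("1", 1, "C", "T", 0.25, "G", "synonymous")]
        full = mutation_burden([make_sample("a", 0, 0, muts)], self.PANEL)
        lower = mutation_burden([make_sample("a", 0, 0, muts)], self.PANEL, double_vaf=False)
        assert full["burden_per_mb"].iloc[0] == pytest.approx(2 * lower["burden_per_mb"].iloc[0])

    def test_indels_never_counted(self):
        muts = [("1", 1, "C", "CT", 0.5, "G", "indel")]
        with pytest.warns(UserWarning):
            df = mutation_burden([make_sample("a", 0, 0, muts)], self.PANEL)
        assert df["burden_per_mb"].iloc[0] == 0.0


class TestCloneDensity:
    @pytest.mark.parametrize(
        "n,area,expected", [(26, 80.0, 0.33), (46, 120.0, 0.38), (0, 120.0, 0.0)]
    )
    def test_worked_examples(self, n, area, expected):
        assert round(clone_density(n, area), 2) == expected

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            clone_density(5, 0.0)


class TestRankTp53Consequence:
    def test_dominant_negative_wins(self):
        calls = [
            MutationCall("11", 1, "C", "T", 0.1, consequence="nonsense"),
            MutationCall("11", 2, "C", "T", 0.1, consequence="missense",
                         protein_change="p.R248W"),
        ]
        assert rank_tp53_consequence(calls) == "dominant_negative"

    def test_stop_gain_only(self):
        calls = [MutationCall("11", 1, "C", "T", 0.1, consequence="nonsense")]
        assert rank_tp53_consequence(calls) == "nonsense"

    def test_missense_over_other(self):
        calls = [
            MutationCall("11", 1, "C", "T", 0.1, consequence="missense"),
            MutationCall("11", 2, "C", "T", 0.1, consequence="essential_splice"),
        ]
        assert rank_tp53_consequence(calls) == "missense"

    def test_empty_is_none(self):
        assert rank_tp53_consequence([]) == "none"

    def test_splice_only_is_other(self):
        calls = [MutationCall("11", 1, "C", "T", 0.1, consequence="essential_splice")]
        assert rank_tp53_consequence(calls) == "other"


def test_vaf_validation():
    with pytest.raises(ValueError):
        MutationCall("1", 1, "C", "T", 1.5)
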