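import numpy as np
import pandas as pd
import pytest

from ripseed.errors import (
    ConfigurationError,
    InsufficientDataError,
    RipseedError,
    UndefinedRatioError,
)
from ripseed.profile_analysis import (
    binned_seed_frequency,
    ecdf,
    exclusive_region_membership,
    rank_genes,
    region_distribution_compare,
    region_flags,
    region_proportions,
    tiling_relative_frequency,
)
from ripseed.seed_scan import CDS, UTR3, UTR5, SeedMatchRecord, tiling_windows
from ripseed.seed_scan import MIR191


def _match(gene, region, pos=1):
    return SeedMatchRecord(gene, region, pos, "TTCCGTT")


class TestRankGenes:
    def test_descending_with_ties_by_gene_id(self):
        v = pd.Series({"g1": 3.0, "g2": 1.0, "g3": 2.0})
        assert rank_genes(v).tolist() == ["g1", "g3", "g2"]
        tied = pd.Series({"z": 1.0, "a": 1.0, "m": 1.0})
        assert rank_genes(tied).tolist() == ["a", "m", "z"]

    def test_single_gene(self):
        assert rank_genes(pd.Series({"only": 5.0})).tolist() == ["only"]

    def test_nan_rejected(self):
        with pytest.raises(RipseedError):
            rank_genes(pd.Series({"a": np.nan, "b": 1.0}))


class TestBinnedSeedFrequency:
    def test_relative_frequency_arithmetic(self):
        """Top bin 100/250 matched vs background 100/500 gives ratio 2."""
        genes = [f"g{i:03d}" for i in range(500)]
        has_match = pd.Series(False, index=genes)
        has_match.iloc[:100] = True  # all matches in the top bin
        profile = binned_seed_frequency(genes, has_match, bin_size=250)
        assert profile.loc[0, "relative_frequency"] == pytest.approx(2.0)
        assert profile.loc[1, "relative_frequency"] == pytest.approx(0.0)

    def test_partial_final_bin_is_flagged(self):
        genes = [f"g{i:03d}" for i in range(600)]
        has_match = pd.Series([True] * 600, index=genes)
        profile = binned_seed_frequency(genes, has_match, bin_size=250)
        assert profile["bin_size"].tolist() == [250, 250, 100]
        assert profile["partial"].tolist() == [False, False, True]

    def test_weighted_mean_of_bin_fractions_is_overall_fraction(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i:03d}" for i in range(613)]
        has_match = pd.Series(rng.random(613) < 0.3, index=genes)
        profile = binned_seed_frequency(genes, has_match, bin_size=100)
        weighted = (profile["n_match"]).sum() / profile["bin_size"].sum()
        assert weighted == pytest.approx(has_match.mean())

    def test_null_permutation_expectation_is_one(self):
        """Random ranking leaves every bin's expected relative frequency ~1."""
        rng = np.random.default_rng(5)
        genes = [f"g{i:03d}" for i in range(500)]
        has_match = pd.Series(rng.random(500) < 0.4, index=genes)
        top = []
        for _ in range(300):
            order = list(rng.permutation(genes))
            prof = binned_seed_frequency(order, has_match, bin_size=250)
            top.append(prof.loc[0, "relative_frequency"])
        assert np.mean(top) == pytest.approx(1.0, abs=0.05)

    def test_zero_background_fraction_raises(self):
        genes = ["a", "b"]
        with pytest.raises(UndefinedRatioError):
            binned_seed_frequency(genes, pd.Series(False, index=genes), 1)


class TestRegionFlagsAndProportions:
    def test_inclusive_counts_gene_in_every_matched_region(self):
        flags = region_flags(
            [_match("a", CDS), _match("b", CDS), _match("b", UTR3),
             _match("c", UTR3)],
            ["a", "b", "c", "d"],
        )
        tbl = region_proportions(flags, "inclusive").set_index("category")
        assert tbl.loc[CDS, "n_genes"] == 2
        assert tbl.loc[CDS, "proportion"] == pytest.approx(0.5)
        assert tbl.loc[UTR3, "n_genes"] == 2

    def test_exclusive_partitions_the_universe(self):
        flags = region_flags(
            [_match("a", CDS), _match("b", CDS), _match("b", UTR3),
             _match("c", UTR3)],
            ["a", "b", "c", "d"],
        )
        tbl = region_proportions(flags, "exclusive").set_index("category")
        assert tbl.loc[CDS, "n_genes"] == 1  # b is multi-region
        assert tbl.loc["multiple", "n_genes"] == 1
        assert tbl.loc["none", "n_genes"] == 1
        assert tbl["n_genes"].sum() == 4
        assert tbl["proportion"].sum() == pytest.approx(1.0)

    def test_empty_match_list_gives_zero_proportions(self):
        flags = region_flags([], ["a", "b"])
        tbl = region_proportions(flags, "inclusive")
        assert (tbl["proportion"] == 0).all()

    def test_match_outside_universe_rejected(self):
        with pytest.raises(ConfigurationError):
            region_flags([_match("ghost", CDS)], ["a"])


class TestEcdf:
    def test_step_points(self):
        out = ecdf([1, 2, 3])
        assert out["cumulative_fraction"].tolist() == pytest.approx(
            [1 / 3, 2 / 3, 1.0]
        )

    def test_duplicates_collapse_into_double_step(self):
        out = ecdf([1, 2, 2, 3])
        assert out["value"].tolist() == [1, 2, 3]
        assert out["cumulative_fraction"].tolist() == pytest.approx(
            [0.25, 0.75, 1.0]
        )

    def test_single_value_and_monotonicity(self):
        assert ecdf([7.0])["cumulative_fraction"].tolist() == [1.0]
        out = ecdf(np.random.default_rng(0).normal(size=100))
        assert (np.diff(out["cumulative_fraction"]) > 0).all()
        assert out["cumulative_fraction"].iloc[-1] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(RipseedError):
            ecdf([])


class TestRegionCompare:
    def test_identical_groups(self):
        vals = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        both = pd.Series(True, index=vals.index)
        res = region_distribution_compare(vals, both, both)
        assert res.result.t == 0.0 and res.result.p == 1.0

    def test_planted_region_effect_is_detected(self):
        """A 0.5 log2-unit CDS-vs-3'UTR effect at sigma 0.5, n=500/group."""
        rng = np.random.default_rng(9)
        idx = [f"g{i:04d}" for i in range(1000)]
        vals = pd.Series(
            np.concatenate([rng.normal(0.5, 0.5, 500), rng.normal(0.0, 0.5, 500)]),
            index=idx,
        )
        in_cds = pd.Series([True] * 500 + [False] * 500, index=idx)
        res = region_distribution_compare(
            vals, in_cds, ~in_cds, alternative="a_greater",
            label_a=CDS, label_b=UTR3,
        )
        assert res.result.mean_a > res.result.mean_b
        assert res.result.p < 0.05

    def test_degenerate_zero_variance_groups(self):
        vals = pd.Series([1.0, 1.0, 2.0, 2.0], index=list("abcd"))
        a = pd.Series([True, True, False, False], index=list("abcd"))
        res = region_distribution_compare(vals, a, ~a, alternative="a_greater")
        assert res.result.degenerate and res.result.p == 1.0

    def test_too_small_group_rejected(self):
        vals = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        a = pd.Series([True, False, False], index=list("abc"))
        with pytest.raises(InsufficientDataError):
            region_distribution_compare(vals, a, ~a)


class TestTiling:
    def test_target_set_equal_to_background_is_flat(self):
        windows = tiling_windows(MIR191, 6)
        utr3 = {
            "a": "TTCCGTTACGT",
            "b": "ACGTACGTACGTACGT",
            "c": "TCCGTTTCCGTT",
        }
        tbl = tiling_relative_frequency(windows, list(utr3), list(utr3), utr3)
        present = tbl["relative_frequency"].dropna()
        assert present.tolist() == pytest.approx([1.0] * len(present))

    def test_window_absent_from_background_is_nan_not_error(self):
        windows = tiling_windows(MIR191, 6)
        utr3 = {"a": "AAAAAAAA"}
        tbl = tiling_relative_frequency(windows, ["a"], ["a"], utr3)
        assert tbl["relative_frequency"].isna().all()

    def test_empty_target_set_rejected(self):
        windows = tiling_windows(MIR191, 6)
        with pytest.raises(RipseedError):
            tiling_relative_frequency(windows, [], ["a"], {"a": "ACGT"})

    def test_missing_utr3_sequence_rejected(self):
        windows = tiling_windows(MIR191, 6)
        with pytest.raises(ConfigurationError):
            tiling_relative_frequency(windows, ["a"], ["a"], {})
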