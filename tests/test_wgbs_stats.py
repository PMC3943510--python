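"""WGBS pairing, noise statistics, density matrix, SD comparisons."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from probeqc.manifest_io import ProbeRecord
from probeqc.synthetic_data import simulate_paired_betas
from probeqc.wgbs_stats import (
    PairedBeta,
    category_beta_distribution,
    category_stats,
    density_matrix,
    flag_unknown_factors,
    load_wgbs_sites,
    pair_probe_wgbs,
    pearson_r,
    per_probe_sd,
    sd_comparison,
    wilcoxon_rank_sum,
)

SEQ = "ACGT" * 12 + "AC"


class TestLoadWgbs:
    def test_coverage_filter_boundary(self, tmp_path):
        p = tmp_path / "w.bedgraph"
        p.write_text("chr1\t100\t101\t50\t4\nchr1\t200\t201\t100\t5\n")
        sites = load_wgbs_sites(p)
        assert ("chr1", 101) not in sites
        assert sites[("chr1", 201)].beta == 1.0
        assert sites[("chr1", 201)].coverage == 5

    def test_four_column_format(self, tmp_path):
        p = tmp_path / "w.tsv"
        p.write_text("chr1\t201\t80\t9\n")
        sites = load_wgbs_sites(p)
        assert sites[("chr1", 201)].beta == pytest.approx(0.8)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "w.bedgraph"
        p.write_text("")
        assert load_wgbs_sites(p) == {}

    def test_score_out_of_range_rejected(self, tmp_path):
        p = tmp_path / "w.bedgraph"
        p.write_text("chr1\t100\t101\t150\t9\n")
        with pytest.raises(ValueError, match="score"):
            load_wgbs_sites(p)

    def test_duplicate_keeps_higher_coverage(self, tmp_path):
        p = tmp_path / "w.bedgraph"
        p.write_text("chr1\t100\t101\t10\t6\nchr1\t100\t101\t90\t30\n")
        sites = load_wgbs_sites(p)
        assert sites[("chr1", 101)].coverage == 30


class TestPairing:
    def test_abs_and_signed_diff(self, tmp_path):
        probe = ProbeRecord("cg01", "I", "chr1", 201, "+", SEQ)
        sites = {("chr1", 201): __import__("probeqc.wgbs_stats", fromlist=["WgbsSite"]).WgbsSite("chr1", 201, 0.5, 10)}
        pairs, unmatched = pair_probe_wgbs([probe], sites, {"cg01": 0.9})
        assert not unmatched
        assert pairs[0].abs_diff == pytest.approx(0.4)
        assert pairs[0].signed_diff == pytest.approx(0.4)

    def test_uncovered_site_unmatched(self):
        probe = ProbeRecord("cg01", "I", "chr1", 201, "+", SEQ)
        pairs, unmatched = pair_probe_wgbs([probe], {}, {"cg01": 0.9})
        assert pairs == [] and unmatched == ["cg01"]

    def test_fixture_matched_count(self, world):
        # every probe gets a WGBS row; pairing fails only below the coverage floor
        truth = world.fixture.truth
        expected = int((truth["wgbs_coverage"] >= 5).sum())
        assert len(world.pairs) == expected


class TestPearson:
    def test_identity_and_antiidentity(self):
        x = [0.1, 0.5, 0.7, 0.9]
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_against_direct_formula(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 5.0])
        xc, yc = x - x.mean(), y - y.mean()
        expected = float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1], [1, 2, 3])


def exact_p_by_enumeration(a, b):
    """Two-sided rank-sum p from full enumeration of group assignments."""
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank().to_numpy()
    na = len(a)
    obs = ranks[:na].sum()
    mean = na * (len(pooled) + 1) / 2.0
    sums = np.array([
        ranks[list(idx)].sum() for idx in itertools.combinations(range(len(pooled)), na)
    ])
    p = np.mean(np.abs(sums - mean) >= abs(obs - mean) - 1e-12)
    return float(p)


class TestWilcoxon:
    def test_identical_samples(self):
        a = [1.0, 2.0, 3.0, 4.0]
        assert wilcoxon_rank_sum(a, a) >= 0.99

    def test_complete_separation_small_n(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_exact_agrees_with_enumeration(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            a = rng.normal(size=5)
            b = rng.normal(size=6)
            p = wilcoxon_rank_sum(a, b, mode="exact")
            assert p == pytest.approx(exact_p_by_enumeration(a, b), abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


class TestCategoryStats:
    def _pairs(self, ids, diffs):
        return [PairedBeta(pid, 0.5 + d, 0.5) for pid, d in zip(ids, diffs)]

    def test_category_equal_background(self):
        rng = np.random.default_rng(5)
        ids = [f"p{i}" for i in range(40)]
        pairs = self._pairs(ids, rng.normal(0, 0.05, size=40))
        stats = category_stats(pairs, ids, ids, "self")
        assert stats.wilcoxon_p >= 0.99

    def test_median_example(self):
        pairs = self._pairs(["a", "b", "c"], [0.1, 0.2, 0.3])
        stats = category_stats(pairs, ["a", "b", "c"], [])
        assert stats.median_abs_diff == pytest.approx(0.2)
        assert stats.n == 3

    def test_empty_category(self):
        stats = category_stats([], ["x"], ["y"])
        assert stats.n == 0 and math.isnan(stats.median_abs_diff)

    def test_inflated_category_detected(self):
        """3x noise inflation at n=500/group is decisively detected."""
        arr_bg, wgbs_bg = simulate_paired_betas(500, 0.05, seed=101)
        arr_cat, wgbs_cat = simulate_paired_betas(500, 0.15, seed=202)
        pairs = [PairedBeta(f"bg{i}", a, w) for i, (a, w) in enumerate(zip(arr_bg, wgbs_bg))]
        pairs += [PairedBeta(f"cat{i}", a, w) for i, (a, w) in enumerate(zip(arr_cat, wgbs_cat))]
        stats = category_stats(pairs, [f"cat{i}" for i in range(500)], [f"bg{i}" for i in range(500)])
        assert stats.wilcoxon_p < 1e-3

    def test_probe_order_invariance(self, world):
        ids = [p.probe_id for p in world.pairs[:100]]
        bg = [p.probe_id for p in world.pairs[100:200]]
        a = category_stats(world.pairs, ids, bg)
        b = category_stats(list(reversed(world.pairs)), ids, bg)
        assert a.n == b.n
        assert np.allclose(
            [a.median_abs_diff, a.pearson_r, a.wilcoxon_p],
            [b.median_abs_diff, b.pearson_r, b.wilcoxon_p],
            equal_nan=True,
        )

    def test_background_isolated_from_other_categories(self):
        rng = np.random.default_rng(9)
        bg_ids = [f"bg{i}" for i in range(50)]
        other_ids = [f"o{i}" for i in range(50)]
        bg_pairs = self._pairs(bg_ids, rng.normal(0, 0.05, size=50))
        clean = bg_pairs + self._pairs(other_ids, rng.normal(0, 0.05, size=50))
        corrupted = bg_pairs + self._pairs(other_ids, rng.normal(0, 0.3, size=50))
        a = category_stats(clean, bg_ids, bg_ids)
        b = category_stats(corrupted, bg_ids, bg_ids)
        assert a.median_abs_diff == b.median_abs_diff
        assert np.isclose(a.pearson_r, b.pearson_r, equal_nan=True)


class TestDensityMatrix:
    def test_boundary_cells_and_conservation(self):
        pairs = [PairedBeta("a", 0.0, 0.0), PairedBeta("b", 1.0, 1.0), PairedBeta("c", 0.5, 0.25)]
        grid = density_matrix(pairs)
        assert grid.shape == (50, 50)
        assert grid[0, 0] == 1  # (0, 0)
        assert grid[49, 49] == 1  # (1, 1) under the closed last bin
        assert grid[12, 25] == 1  # row = wgbs bin, column = array bin
        assert grid.sum() == len(pairs)


class TestUnknownFactors:
    def test_strict_threshold(self):
        pairs = [PairedBeta("at", 0.60, 0.30), PairedBeta("over", 0.61, 0.30)]
        assert flag_unknown_factors(pairs) == {"over"}

    def test_concordant_fixture_empty(self):
        pairs = [PairedBeta(f"p{i}", 0.5, 0.5) for i in range(10)]
        assert flag_unknown_factors(pairs) == set()


class TestPerProbeSd:
    def test_examples(self):
        m = pd.DataFrame(
            {"s1": [0.5, 0.0, 0.3], "s2": [0.5, 1.0, np.nan]},
            index=["const", "spread", "single"],
        )
        sds = per_probe_sd(m)
        assert sds["const"] == 0.0
        assert sds["spread"] == pytest.approx(math.sqrt(0.5))
        assert "single" not in sds.index


class TestSdComparison:
    def test_separated_groups(self):
        rng = np.random.default_rng(30)
        keep = pd.Series(np.abs(rng.normal(0.05, 0.01, size=300)), index=[f"k{i}" for i in range(300)])
        discard = pd.Series(np.abs(rng.normal(0.15, 0.02, size=300)), index=[f"d{i}" for i in range(300)])
        sds = pd.concat([keep, discard])
        result = sd_comparison(sds, keep.index, discard.index)
        assert result["p_value"] < 1e-10
        assert result["keep"]["median_sd"] < result["discard"]["median_sd"]

    def test_min_sd_filter_counts(self):
        sds = pd.Series([0.05, 0.15, 0.25], index=["a", "b", "c"])
        result = sd_comparison(sds, ["a", "b"], ["c"], min_sd=0.10)
        assert result["keep"]["n"] == 2 and result["keep"]["n_ge_min"] == 1

    def test_overlapping_groups_rejected(self):
        sds = pd.Series([0.1, 0.2], index=["a", "b"])
        with pytest.raises(ValueError):
            sd_comparison(sds, ["a"], ["a", "b"])


class TestCategoryBetaDistribution:
    def test_mass_in_last_bin(self):
        m = pd.DataFrame({"s1": [0.975, 0.975]}, index=["a", "b"])
        hist = category_beta_distribution(m, ["a", "b"])
        assert hist.iloc[-1] == 2 and hist.sum() == 2

    def test_conservation_with_missing(self):
        m = pd.DataFrame({"s1": [0.2, np.nan], "s2": [0.8, 0.5]}, index=["a", "b"])
        hist = category_beta_distribution(m, ["a", "b"])
        assert hist.sum() == 3


class TestSignedDiffBias:
    def test_symmetric_noise_centers_at_zero(self):
        arr, wgbs = simulate_paired_betas(20_000, 0.03, seed=77)
        assert abs(np.mean(arr - wgbs)) < 0.01

    def test_injected_array_bias_recovered(self):
        """A +0.05 array offset shifts the mean signed difference by ~+0.05."""
        arr0, wgbs0 = simulate_paired_betas(20_000, 0.03, seed=78)
        arr1, wgbs1 = simulate_paired_betas(20_000, 0.03, seed=78, array_bias=0.05)
        shift = np.mean(arr1 - wgbs1) - np.mean(arr0 - wgbs0)
        assert shift == pytest.approx(0.05, abs=0.015)
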