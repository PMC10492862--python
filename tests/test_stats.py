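"""ANOVA, Fisher combination, KS, BH and overlap summaries vs oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats as sps

from acetylstoich.stats import (
    OverlapSummary,
    anova_oneway,
    bh_fdr,
    compare_models,
    fisher_combine,
    group_comparison,
    ks_two_sample,
    site_presence,
)


def anova_by_sums_of_squares(groups):
    """Independent oracle: textbook between/within sum-of-squares arithmetic."""
    all_values = [v for g in groups for v in g]
    grand = sum(all_values) / len(all_values)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    df_b = len(groups) - 1
    df_w = len(all_values) - len(groups)
    return (ssb / df_b) / (ssw / df_w)


def chi2_sf_by_quadrature(x, df):
    """Upper-tail chi-square probability by direct numerical integration."""
    def pdf(t):
        return t ** (df / 2 - 1) * math.exp(-t / 2) / (
            2 ** (df / 2) * math.gamma(df / 2)
        )
    value, _ = integrate.quad(pdf, x, np.inf)
    return value


class TestAnova:
    def test_worked_example_f_equals_three(self):
        f, p = anova_oneway([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert f == pytest.approx(3.0, abs=1e-12)
        assert p == pytest.approx(sps.f.sf(3.0, 2, 6), abs=1e-12)

    def test_identical_groups_no_signal(self):
        f, p = anova_oneway([[1, 2, 3], [1, 2, 3]])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_two_groups_equals_squared_t(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=6), rng.normal(1.0, size=7)
        f, p_f = anova_oneway([a, b])
        t, p_t = sps.ttest_ind(a, b)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    @given(st.data())
    @settings(deadline=None, max_examples=60)
    def test_matches_sum_of_squares_oracle(self, data):
        n_groups = data.draw(st.integers(2, 4))
        groups = [
            data.draw(
                st.lists(
                    st.floats(-5, 5, allow_nan=False), min_size=2, max_size=8
                )
            )
            for _ in range(n_groups)
        ]
        values = np.array([v for g in groups for v in g])
        # degenerate all-equal inputs are handled separately (F=0 convention)
        if np.ptp(values) == 0 or any(np.ptp(g) == 0 for g in map(np.array, groups)):
            return
        f, _ = anova_oneway(groups)
        assert f == pytest.approx(anova_by_sums_of_squares(groups), abs=1e-10)

    def test_insufficient_replication_rejected(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0], [2.0, 3.0]])


class TestFisher:
    def test_single_p_identity(self):
        assert fisher_combine([0.2]) == pytest.approx(0.2, abs=1e-12)

    def test_all_ones_give_one(self):
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)

    def test_two_p05_against_quadrature(self):
        x = -2 * (math.log(0.05) + math.log(0.05))
        expected = chi2_sf_by_quadrature(x, 4)
        assert fisher_combine([0.05, 0.05]) == pytest.approx(expected, abs=1e-10)
        assert fisher_combine([0.05, 0.05]) == pytest.approx(0.0175, abs=1e-3)

    @given(st.floats(1e-6, 1.0))
    @settings(deadline=None, max_examples=50)
    def test_adding_a_null_p_weakens_evidence(self, p):
        assert fisher_combine([p, 1.0]) >= fisher_combine([p, p])

    def test_zero_p_floored(self):
        assert 0 < fisher_combine([0.0, 0.5]) < 1e-100

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([])


class TestKs:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0

    def test_worked_interleaved_example(self):
        d, _ = ks_two_sample([1, 2, 3, 4], [1.5, 2.5, 3.5, 4.5])
        assert d == pytest.approx(0.25)

    def test_disjoint_supports(self):
        d, p = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert d == 1.0
        assert p < 0.11  # exact two-sided p for n=m=3 complete separation

    def test_matches_hand_ecdf_supremum(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=30), rng.normal(0.5, size=25)
        grid = np.concatenate([x, y])
        ecdf_x = np.array([(x <= g).mean() for g in grid])
        ecdf_y = np.array([(y <= g).mean() for g in grid])
        d, _ = ks_two_sample(x, y)
        assert d == pytest.approx(np.abs(ecdf_x - ecdf_y).max(), abs=1e-12)


class TestBh:
    def test_worked_example_all_collapse(self):
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3]) == pytest.approx([0.3])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=60)
    def test_adjusted_at_least_raw_and_bounded(self, ps):
        adjusted = bh_fdr(ps)
        assert np.all(adjusted >= np.asarray(ps) - 1e-12)
        assert np.all(adjusted <= 1.0 + 1e-12)

    def test_fdr_control_in_null_simulation(self, rng):
        """Thresholding BH-adjusted p at q keeps simulated FDR near q."""
        q = 0.1
        fdps = []
        for _ in range(200):
            p_null = rng.uniform(size=60)
            p_alt = rng.uniform(size=20) * 1e-4
            ps = np.concatenate([p_null, p_alt])
            rejected = bh_fdr(ps) < q
            n_rej = rejected.sum()
            fdps.append(rejected[:60].sum() / n_rej if n_rej else 0.0)
        assert np.mean(fdps) <= q + 0.02


def comparison_frame(sites):
    rows = [
        {"protein_id": p, "site_position": i, "p_site": p_val, "mean_WT": 0.5}
        for (p, i, p_val) in sites
    ]
    return pd.DataFrame(rows)


class TestCompareModels:
    def test_set_algebra(self):
        a = comparison_frame(
            [("P1", 1, 0.01), ("P2", 1, 0.01), ("P3", 1, 0.01), ("P4", 1, 0.5)]
        )
        b = comparison_frame(
            [("P2", 1, 0.01), ("P3", 1, 0.01), ("P5", 1, 0.01), ("P1", 1, 0.9)]
        )
        ov = compare_models(a, b, alpha=0.05, reference="WT")
        assert ov.sites_shared == 2
        assert ov.sites_unique_a == 1
        assert ov.sites_unique_b == 1
        assert ov.sites_total_a == 3

    def test_identical_tables_fully_shared(self):
        a = comparison_frame([("P1", 1, 0.01), ("P2", 2, 0.02)])
        ov = compare_models(a, a.copy())
        assert ov.sites_unique_a == ov.sites_unique_b == 0
        assert ov.sites_shared == 2

    def test_mismatched_reference_rejected(self):
        a = comparison_frame([("P1", 1, 0.01)])
        b = a.drop(columns=["mean_WT"])
        with pytest.raises(ValueError, match="reference"):
            compare_models(a, b, reference="WT")


class TestGroupComparison:
    def test_detects_planted_shifts(self, small_study, small_quantified):
        b, q = small_study, small_quantified
        res = group_comparison(
            q.peptidoforms, q.sites, groups=["WT", "sTgA"], reference="WT"
        )
        merged = res.merge(
            b.truth[["protein_id", "site_position", "effect_flag"]],
            on=["protein_id", "site_position"],
        )
        affected = merged["effect_flag"].isin(["shared", "model_a_only"])
        power = merged.loc[affected, "significant"].mean()
        fpr = merged.loc[~affected, "significant"].mean()
        assert power > 0.6
        assert fpr < 0.15
        # delta tracks the planted direction
        sig = merged[affected & merged["significant"]]
        truth_delta = (
            b.truth.set_index(["protein_id", "site_position"])
            .loc[list(zip(sig["protein_id"], sig["site_position"]))]
        )
        assert np.all(
            np.sign(sig["delta"].to_numpy())
            == np.sign((truth_delta["s_sTgA"] - truth_delta["s_WT"]).to_numpy())
        )

    def test_reference_must_be_in_groups(self, small_quantified):
        q = small_quantified
        with pytest.raises(ValueError, match="reference"):
            group_comparison(q.peptidoforms, q.sites, ["sTgA", "sTgB"], "WT")

    def test_presence_table_counts_all_sites(self, small_quantified):
        q = small_quantified
        presence = site_presence(q.sites, ["WT", "sTgA", "sTgB"])
        n_sites = q.sites.groupby(["protein_id", "site_position"]).ngroups
        assert len(presence) == n_sites
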