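"""Frequencies, ES regression, replicate averaging, Z-scores, correlations."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from dockscreen import (ScreenModel, SimulationConfig, assign_fitness,
                        average_replicates, build_synthetic_library,
                        frequencies, screen_correlation, simulate_selection,
                        zscores)
from dockscreen.enrichment import ScreenError, _ols_slopes
from conftest import make_count_table


class TestFrequencies:
    def test_plain_division_without_pseudocount(self):
        table = make_count_table({"A": [100, 100], "B": [300, 300]},
                                 doublings=[0, 2])
        fm = frequencies(table, pseudocount=0.0)
        assert np.allclose(fm.F.iloc[:, 0], [0.25, 0.75])

    def test_pseudocount_arithmetic(self):
        table = make_count_table({"A": [0, 0], "B": [100, 100]},
                                 doublings=[0, 2])
        fm = frequencies(table, pseudocount=0.5)
        assert np.allclose(fm.F.iloc[:, 0], [0.5 / 101, 100.5 / 101])

    def test_uniform_counts_uniform_frequencies(self):
        table = make_count_table({m: [50, 50] for m in "ABCDE"},
                                 doublings=[0, 2])
        for pc in (0.0, 0.5, 2.0):
            fm = frequencies(table, pseudocount=pc)
            assert np.allclose(fm.F.to_numpy(), 0.2)

    def test_columns_sum_to_one(self, small_table):
        fm = frequencies(small_table)
        assert np.allclose(fm.F.sum(axis=0), 1.0, atol=1e-12)

    def test_all_zero_sample_rejected(self):
        table = make_count_table({"A": [10, 0], "B": [10, 0]},
                                 doublings=[0, 2])
        with pytest.raises(ScreenError, match="all-zero"):
            frequencies(table)

    def test_baseline_zero_flagged(self):
        table = make_count_table({"A": [0, 50], "B": [100, 50]},
                                 doublings=[0, 2])
        fm = frequencies(table)
        assert fm.baseline_zero.loc["A"].all()
        assert not fm.baseline_zero.loc["B"].any()


class TestEnrichmentScores:
    def test_constant_frequencies_give_zero_es(self):
        table = make_count_table({"A": [100, 100, 100], "B": [300, 300, 300]},
                                 doublings=[0, 2, 4])
        scores = ScreenModel(table, pseudocount=0.0).fit()
        assert np.allclose(scores.per_replicate["es"], 0.0)

    def test_two_point_closed_form(self):
        # F ratio of 2 over 2 doublings: ES = ln(2)/2 exactly
        table = make_count_table({"A": [50, 100], "B": [150, 100]},
                                 doublings=[0, 2])
        scores = ScreenModel(table, pseudocount=0.0).fit()
        es = scores.per_replicate.set_index("member_id")["es"]
        assert es["A"] == pytest.approx(np.log(2) / 2, abs=1e-12)

    def test_slopes_match_statsmodels(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            n_t = rng.integers(3, 6)
            D = np.sort(np.concatenate([[0.0], rng.uniform(0.5, 7, n_t - 1)]))
            counts = {f"M{i}": rng.integers(1, 500, len(D)).tolist()
                      for i in range(6)}
            table = make_count_table(counts, doublings=D.tolist())
            scores = ScreenModel(table, pseudocount=0.5).fit()
            fm = frequencies(table, 0.5)
            base = table.counts.columns[0]
            for mid in counts:
                y = np.log(fm.F.loc[mid] / fm.F.loc[mid, base]).to_numpy()
                ols = sm.OLS(y, sm.add_constant(D)).fit()
                got = scores.per_replicate.set_index("member_id").loc[mid, "es"]
                assert got == pytest.approx(ols.params[1], abs=1e-10)

    def test_closed_form_textbook_formula(self):
        rng = np.random.default_rng(3)
        D = np.array([0.0, 1.75, 3.5, 5.25, 7.0])
        Y = rng.normal(size=(40, 5))
        slope, intercept, stderr, r2 = _ols_slopes(D, Y)
        Dc = D - D.mean()
        for i in range(len(Y)):
            yc = Y[i] - Y[i].mean()
            assert slope[i] == pytest.approx((Dc @ yc) / (Dc @ Dc), abs=1e-12)

    def test_baseline_zero_member_missing_not_zero(self):
        table = make_count_table({"A": [0, 80, 90], "B": [100, 60, 50],
                                  "C": [100, 60, 60]},
                                 doublings=[0, 2, 4])
        scores = ScreenModel(table).fit()
        es = scores.per_replicate.set_index("member_id")["es"]
        assert np.isnan(es["A"]) and not np.isnan(es["B"])

    def test_depth_invariance(self):
        rng = np.random.default_rng(9)
        D = [0, 2, 4, 6]
        counts = {f"M{i}": (rng.integers(50, 5000, size=4)).tolist()
                  for i in range(20)}
        scaled = {m: [10 * c for c in v] for m, v in counts.items()}
        es_a = ScreenModel(make_count_table(counts, D), pseudocount=0.0).fit() \
            .per_replicate.set_index("member_id")["es"]
        es_b = ScreenModel(make_count_table(scaled, D), pseudocount=0.0).fit() \
            .per_replicate.set_index("member_id")["es"]
        assert np.allclose(es_a, es_b, atol=1e-12)
        # default pseudocount: invariance within 1e-3 at depth >= 1e4
        es_c = ScreenModel(make_count_table(counts, D), pseudocount=0.5).fit() \
            .per_replicate.set_index("member_id")["es"]
        es_d = ScreenModel(make_count_table(scaled, D), pseudocount=0.5).fit() \
            .per_replicate.set_index("member_id")["es"]
        assert np.abs(es_c - es_d).max() < 1e-3

    def test_es_brackets_zero(self, small_scores):
        """Frequencies sum to 1, so enrichment of some members forces
        depletion of others."""
        for (_, _, _), grp in small_scores.per_replicate.groupby(
                ["genotype", "condition", "replicate"]):
            es = grp["es"].dropna()
            if es.nunique() > 1:
                assert es.min() <= 0 <= es.max()

    def test_selective_dispersion_exceeds_nonselective(self, small_scores):
        sel = small_scores.scores.query("condition == 'selective'")
        non = small_scores.scores.query("condition == 'nonselective'")
        for g in sel["genotype"].unique():
            assert (sel[sel.genotype == g]["mean_es"].std()
                    > non[non.genotype == g]["mean_es"].std())


class TestAveragingAndZ:
    def test_average_simple(self):
        df = pd.DataFrame({
            "genotype": "WT", "condition": "selective",
            "replicate": [1, 2, 3], "member_id": "A",
            "es": [0.1, 0.2, 0.3]})
        out = average_replicates(df)
        assert out["mean_es"].iloc[0] == pytest.approx(0.2)
        assert out["n_replicates_used"].iloc[0] == 3

    def test_average_skips_missing(self):
        df = pd.DataFrame({
            "genotype": "WT", "condition": "selective",
            "replicate": [1, 2, 3], "member_id": "A",
            "es": [0.5, np.nan, 0.1]})
        out = average_replicates(df)
        assert out["mean_es"].iloc[0] == pytest.approx(0.3)
        assert out["n_replicates_used"].iloc[0] == 2

    def test_average_all_missing_stays_missing(self):
        df = pd.DataFrame({
            "genotype": "WT", "condition": "selective",
            "replicate": [1, 2], "member_id": "A", "es": [np.nan, np.nan]})
        out = average_replicates(df)
        assert np.isnan(out["mean_es"].iloc[0])
        assert out["n_replicates_used"].iloc[0] == 0

    def test_zscore_closed_form(self):
        z = zscores(pd.Series([1.0, 2.0, 3.0], index=list("ABC")))
        assert np.allclose(z, [-1, 0, 1])

    def test_zscore_normalization(self):
        rng = np.random.default_rng(12)
        z = zscores(pd.Series(rng.normal(2, 5, size=200)))
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1) < 1e-9

    def test_extreme_member_exceeds_three(self):
        vals = pd.Series(np.concatenate([np.random.default_rng(0).normal(0, 1, 50),
                                         [40.0]]))
        assert zscores(vals).iloc[-1] > 3

    def test_degenerate_screen_rejected(self):
        with pytest.raises(ScreenError, match="degenerate"):
            zscores(pd.Series([1.0, 1.0, 1.0]))

    def test_too_few_members_rejected(self):
        with pytest.raises(ScreenError):
            zscores(pd.Series([1.0]))


class TestCorrelation:
    def test_identical_vectors(self):
        a = pd.Series([0.1, 0.5, -0.2, 0.9], index=list("ABCD"))
        r, n = screen_correlation(a, a)
        assert r == pytest.approx(1.0) and n == 4

    def test_anti_ordered_affine(self):
        a = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("ABCD"))
        r, _ = screen_correlation(a, -2 * a + 7)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_five_members(self):
        a = pd.Series([1.0, 2, 3, 4, 5], index=list("ABCDE"))
        b = pd.Series([2.0, 1, 4, 3, 6], index=list("ABCDE"))
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        expected = cov / (a.std(ddof=0) * b.std(ddof=0))
        r, n = screen_correlation(a, b)
        assert r == pytest.approx(expected, abs=1e-12) and n == 5

    def test_intersection_only(self):
        a = pd.Series([1.0, 2, 3, np.nan], index=list("ABCD"))
        b = pd.Series([1.0, 2, 3, 4], index=list("ABCD"))
        _, n = screen_correlation(a, b)
        assert n == 3

    def test_too_few_shared_rejected(self):
        a = pd.Series([1.0, 2], index=list("AB"))
        with pytest.raises(ScreenError, match="shared"):
            screen_correlation(a, a)


class TestModelSurface:
    def test_summary_mentions_screens(self, small_scores):
        text = small_scores.summary()
        assert "WT / selective" in text and "pseudocount" in text

    def test_tsv_round_trip(self, small_scores, tmp_path):
        from dockscreen import ScreenScores
        small_scores.write_tsv(tmp_path / "s")
        back = ScreenScores.read_tsv(tmp_path / "s")
        pd.testing.assert_frame_equal(
            back.scores, small_scores.scores, check_exact=False, atol=1e-12)

    def test_hits_accessor_matches_call_hits(self, small_scores):
        from dockscreen import call_hits
        z = small_scores.z("WT", "selective")
        assert small_scores.hits("WT") == call_hits(z, 3.0)
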