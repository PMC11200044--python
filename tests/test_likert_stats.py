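"""Likert construct statistics against hand computations and library oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clinpath.errors import (
    ConfigurationError,
    DegenerateDataError,
    EmptyGroupError,
    InsufficientDataError,
)
from clinpath.likert_stats import (
    LikertDataset,
    agreement_scores,
    collinearity_vif,
    construct_agreement,
    construct_scores,
    convergent_validity,
    cronbach_alpha,
    descriptives,
    exact_mann_whitney_p,
    htmt,
    htmt_matrix,
    mann_whitney_u,
    pearson_matrix,
    u_from_mean_ranks,
)


class TestConstructScores:
    def test_sums_match_row_oracle(self, tiny_likert):
        scores = construct_scores(tiny_likert)
        expected_quality = tiny_likert.scores[["q1", "q2"]].sum(axis=1)
        pd.testing.assert_series_equal(
            scores["quality"], expected_quality, check_names=False
        )

    def test_uniform_scores_sum_to_item_count_times_value(self, tiny_likert):
        data = LikertDataset(
            scores=pd.DataFrame(1, index=tiny_likert.scores.index, columns=tiny_likert.items),
            construct_map=tiny_likert.construct_map,
            site=tiny_likert.site,
        )
        scores = construct_scores(data)
        assert (scores["quality"] == 2).all() and (scores["use"] == 2).all()

    def test_missing_item_excludes_respondent_listwise(self, tiny_likert):
        frame = tiny_likert.scores.astype(float)
        frame.loc["r0", "q1"] = np.nan
        data = LikertDataset(
            scores=frame,
            construct_map=tiny_likert.construct_map,
            site=tiny_likert.site,
        )
        scores = construct_scores(data)
        assert np.isnan(scores.loc["r0", "quality"])
        assert scores.loc["r0", "use"] == frame.loc["r0", ["q3", "q4"]].sum()


class TestAgreement:
    def test_item_fraction_counts_4_and_5(self, tiny_likert):
        ag = agreement_scores(tiny_likert)
        # q1 = [4,5,3,4,5,2] -> 4 of 6
        assert ag.item_level["q1"] == pytest.approx(4 / 6)

    def test_all_fives_gives_ones(self, tiny_likert):
        data = LikertDataset(
            scores=pd.DataFrame(5, index=tiny_likert.scores.index, columns=tiny_likert.items),
            construct_map=tiny_likert.construct_map,
            site=tiny_likert.site,
        )
        ag = agreement_scores(data)
        assert (ag.item_level == 1.0).all() and (ag.construct_level == 1.0).all()

    def test_construct_level_is_mean_of_items(self, tiny_likert):
        ag = agreement_scores(tiny_likert)
        assert ag.construct_level["quality"] == pytest.approx(
            (ag.item_level["q1"] + ag.item_level["q2"]) / 2
        )

    def test_four_respondent_half_agreement(self):
        level = construct_agreement({"i1": 0.5}, {"i1": "c"})
        assert level["c"] == 0.5

    def test_empty_selection_raises(self, tiny_likert):
        with pytest.raises(EmptyGroupError):
            agreement_scores(tiny_likert, site="nowhere")


class TestMannWhitney:
    def test_published_group_rank_identity(self):
        """Printed mean ranks + sizes recover the printed U within rounding."""
        assert u_from_mean_ranks(42, 31, 32.70, 42.82) == pytest.approx(470.5, abs=0.5)
        assert u_from_mean_ranks(42, 31, 31.04, 45.08) == pytest.approx(400.5, abs=0.5)

    def test_u_complement_identity(self):
        rng = np.random.default_rng(0)
        a, b = rng.integers(1, 6, 12), rng.integers(1, 6, 9)
        res = mann_whitney_u(a, b)
        assert res.u_a + res.u_b == pytest.approx(len(a) * len(b))

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.integers(1, 6, 10), rng.integers(1, 6, 7)
        r1, r2 = mann_whitney_u(a, b), mann_whitney_u(b, a)
        assert r1.u == pytest.approx(r2.u)
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided)
        assert r1.u_a == pytest.approx(len(a) * len(b) - r2.u_a)

    def test_identical_constant_groups(self):
        res = mann_whitney_u([3, 3, 3], [3, 3])
        assert res.u == pytest.approx(3.0)  # n_a*n_b/2
        assert res.p_two_sided == 1.0

    def test_extreme_separation(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert min(res.u_a, res.u_b) == 0
        # exact enumeration over C(4,2)=6 assignments: the split is extreme
        assert exact_mann_whitney_p([1, 2], [3, 4]) == pytest.approx(2 / 6)

    def test_scipy_asymptotic_agreement(self):
        """Cross-check U and p against scipy's tie-corrected asymptotic test."""
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(7)
        for _ in range(10):
            a = rng.integers(1, 6, int(rng.integers(5, 30)))
            b = rng.integers(1, 6, int(rng.integers(5, 30)))
            ours = mann_whitney_u(a, b)
            ref = mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=False
            )
            assert ours.u_a == pytest.approx(len(a) * len(b) - ref.statistic)
            assert ours.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_asymptotic_close_to_exact_permutation_small_n(self, seed):
        """The no-continuity normal approximation tracks the permutation
        distribution (mid-p convention, the matching comparison point for an
        uncorrected z on a discrete null) at group sizes <= 6."""
        rng = np.random.default_rng(seed)
        a = rng.normal(size=int(rng.integers(4, 7)))
        b = rng.normal(size=int(rng.integers(4, 7)))
        asym = mann_whitney_u(a, b).p_two_sided
        exact_mid = exact_mann_whitney_p(a, b, convention="mid")
        assert abs(asym - exact_mid) < 0.05

    def test_empty_group_raises(self):
        with pytest.raises(EmptyGroupError):
            mann_whitney_u([], [1, 2])


class TestPearson:
    def test_unit_diagonal_and_linear_pair(self):
        x = np.arange(10.0)
        frame = pd.DataFrame({"a": x, "b": 2 * x + 3, "c": np.cos(x)})
        res = pearson_matrix(frame)
        assert res.matrix.loc["a", "a"] == 1.0
        assert res.matrix.loc["a", "b"] == pytest.approx(1.0)

    def test_hand_computed_correlation(self):
        a = np.array([1, 2, 3, 4, 5.0])
        b = np.array([2, 1, 4, 3, 5.0])
        frame = pd.DataFrame({"a": a, "b": b})
        cov = np.sum((a - a.mean()) * (b - b.mean())) / 4
        r = cov / (a.std(ddof=1) * b.std(ddof=1))
        assert pearson_matrix(frame).matrix.loc["a", "b"] == pytest.approx(r)

    def test_zero_variance_flagged_not_zeroed(self):
        frame = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 2, 2, 2]})
        res = pearson_matrix(frame)
        assert res.degenerate == ["b"]
        assert np.isnan(res.matrix.loc["a", "b"])

    def test_too_few_complete_pairs_raises(self):
        frame = pd.DataFrame({"a": [1.0, np.nan, 3], "b": [np.nan, 2.0, 3]})
        with pytest.raises(InsufficientDataError):
            pearson_matrix(frame)


class TestCronbach:
    def test_duplicated_item_is_perfectly_consistent(self):
        x = pd.DataFrame({"a": [1, 2, 3, 4, 5], "b": [1, 2, 3, 4, 5]})
        assert cronbach_alpha(x) == pytest.approx(1.0)

    def test_hand_computed_three_item_matrix(self):
        x = pd.DataFrame(
            {"a": [2, 4, 3, 5, 1], "b": [3, 4, 2, 5, 2], "c": [1, 5, 4, 4, 2]}
        )
        k = 3
        item_var = x.var(ddof=1).sum()
        total_var = x.sum(axis=1).var(ddof=1)
        expected = k / (k - 1) * (1 - item_var / total_var)
        assert cronbach_alpha(x) == pytest.approx(expected)

    def test_independent_items_alpha_near_zero(self):
        rng = np.random.default_rng(11)
        x = pd.DataFrame(rng.integers(1, 6, size=(10_000, 2)), columns=["a", "b"])
        assert abs(cronbach_alpha(x)) < 0.05

    def test_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        base = rng.normal(size=200)
        x = pd.DataFrame(
            {f"i{j}": base + rng.normal(scale=0.8, size=200) for j in range(4)}
        )
        ours = cronbach_alpha(x)
        theirs = pingouin.cronbach_alpha(data=x)[0]
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_invariances(self):
        rng = np.random.default_rng(5)
        x = pd.DataFrame(rng.integers(1, 6, size=(40, 3)), columns=list("abc"))
        assert cronbach_alpha(x[["c", "a", "b"]]) == pytest.approx(cronbach_alpha(x))
        assert cronbach_alpha(x + 7) == pytest.approx(cronbach_alpha(x))

    def test_error_conditions(self):
        with pytest.raises(InsufficientDataError):
            cronbach_alpha(pd.DataFrame({"a": [1, 2, 3]}))
        with pytest.raises(DegenerateDataError):
            cronbach_alpha(pd.DataFrame({"a": [2, 2], "b": [3, 3]}))


class TestConvergentValidity:
    def test_perfect_indicators(self):
        cv = convergent_validity({"a": 1.0, "b": 1.0})
        assert cv.ave == pytest.approx(1.0) and cv.rho_c == pytest.approx(1.0)

    def test_formula_on_printed_style_loadings(self):
        cv = convergent_validity({"a": 0.934, "b": 0.944})
        lam = np.array([0.934, 0.944])
        assert cv.ave == pytest.approx(np.mean(lam**2))
        assert cv.rho_c == pytest.approx(
            lam.sum() ** 2 / (lam.sum() ** 2 + np.sum(1 - lam**2))
        )

    def test_sub_threshold_item_dropped(self):
        cv = convergent_validity({"a": 0.69, "b": 0.90}, threshold=0.70)
        assert cv.dropped == ["a"] and cv.retained == ["b"]

    def test_all_dropped_is_warning_state(self):
        cv = convergent_validity({"a": 0.2, "b": 0.3})
        assert cv.empty and np.isnan(cv.ave)

    def test_low_ave_flagged(self):
        cv = convergent_validity({"a": 0.70, "b": 0.70})
        assert cv.ave == pytest.approx(0.49, abs=1e-12)
        assert not cv.ave_acceptable


class TestHtmt:
    def _dataset(self, frame):
        cmap = {c: ("c1" if c.startswith("x") else "c2") for c in frame.columns}
        return LikertDataset(
            scores=frame,
            construct_map=cmap,
            site=pd.Series("a", index=frame.index),
            scale="continuous",
        )

    def test_identical_homogeneous_blocks_give_unity(self):
        # With homogeneous blocks (duplicate items) a copied construct has
        # all within- and cross-block correlations equal to 1, so HTMT = 1.
        rng = np.random.default_rng(2)
        base = rng.normal(size=200)
        frame = pd.DataFrame({"x1": base, "x2": base, "y1": base, "y2": base})
        assert htmt(self._dataset(frame), "c1", "c2") == pytest.approx(1.0)

    def test_hand_computed_two_plus_two(self):
        rng = np.random.default_rng(4)
        f = rng.normal(size=300)
        frame = pd.DataFrame(
            {
                "x1": f + rng.normal(scale=0.5, size=300),
                "x2": f + rng.normal(scale=0.5, size=300),
                "y1": 0.5 * f + rng.normal(scale=0.8, size=300),
                "y2": 0.5 * f + rng.normal(scale=0.8, size=300),
            }
        )
        corr = frame.corr()
        hetero = np.mean(
            [abs(corr.loc[i, j]) for i in ("x1", "x2") for j in ("y1", "y2")]
        )
        mono = np.sqrt(abs(corr.loc["x1", "x2"]) * abs(corr.loc["y1", "y2"]))
        data = self._dataset(frame)
        assert htmt(data, "c1", "c2") == pytest.approx(hetero / mono)
        assert htmt(data, "c1", "c2") == pytest.approx(htmt(data, "c2", "c1"))

    def test_orthogonal_factors_near_zero(self):
        rng = np.random.default_rng(6)
        f1, f2 = rng.normal(size=10_000), rng.normal(size=10_000)
        frame = pd.DataFrame(
            {
                "x1": f1 + rng.normal(scale=0.6, size=10_000),
                "x2": f1 + rng.normal(scale=0.6, size=10_000),
                "y1": f2 + rng.normal(scale=0.6, size=10_000),
                "y2": f2 + rng.normal(scale=0.6, size=10_000),
            }
        )
        assert abs(htmt(self._dataset(frame), "c1", "c2")) < 0.05

    def test_single_item_construct_rejected(self, tiny_likert):
        data = LikertDataset(
            scores=tiny_likert.scores,
            construct_map={"q1": "solo", "q2": "rest", "q3": "rest", "q4": "rest"},
            site=tiny_likert.site,
        )
        with pytest.raises(InsufficientDataError):
            htmt(data, "solo", "rest")

    def test_matrix_symmetric_and_flagging(self, tiny_likert):
        res = htmt_matrix(tiny_likert, threshold=0.0)
        m = res.matrix
        assert m.loc["quality", "use"] == pytest.approx(m.loc["use", "quality"])
        assert ("quality", "use") in res.flagged  # threshold 0 flags everything


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(60, 3))
        q, _ = np.linalg.qr(x - x.mean(axis=0))  # centered, orthogonal columns
        frame = pd.DataFrame(q, columns=["a", "b", "c"])
        frame["y"] = rng.normal(size=60)
        vif = collinearity_vif(frame, target="y")
        assert np.allclose(vif.to_numpy(), 1.0, atol=1e-10)

    def test_duplicated_predictor_infinite(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=50)
        frame = pd.DataFrame({"a": a, "b": a, "c": rng.normal(size=50), "y": a})
        vif = collinearity_vif(frame, target="y")
        assert np.isinf(vif["a"]) and np.isinf(vif["b"])

    def test_statsmodels_oracle(self):
        sm_inf = pytest.importorskip("statsmodels.stats.outliers_influence")
        import statsmodels.api as sm

        rng = np.random.default_rng(12)
        a = rng.normal(size=80)
        frame = pd.DataFrame(
            {
                "a": a,
                "b": 0.6 * a + rng.normal(scale=0.8, size=80),
                "c": rng.normal(size=80),
                "y": rng.normal(size=80),
            }
        )
        ours = collinearity_vif(frame, target="y")
        design = sm.add_constant(frame[["a", "b", "c"]]).to_numpy()
        for j, name in enumerate(["a", "b", "c"], start=1):
            ref = sm_inf.variance_inflation_factor(design, j)
            assert ours[name] == pytest.approx(ref, rel=1e-8)


class TestDatasetIO:
    def test_csv_round_trip(self, tiny_likert, tmp_path):
        scores = tmp_path / "responses.csv"
        cmap = tmp_path / "constructs.json"
        tiny_likert.to_csv(scores, cmap)
        loaded = LikertDataset.from_csv(scores, cmap)
        pd.testing.assert_frame_equal(
            loaded.scores, tiny_likert.scores, check_dtype=False
        )
        assert loaded.construct_map == tiny_likert.construct_map
        assert list(loaded.site) == list(tiny_likert.site)

    def test_out_of_range_score_rejected(self, tiny_likert):
        bad = tiny_likert.scores.copy()
        bad.loc["r0", "q1"] = 6
        with pytest.raises(Exception) as exc:
            LikertDataset(
                scores=bad,
                construct_map=tiny_likert.construct_map,
                site=tiny_likert.site,
            )
        assert "q1" in str(exc.value)

    def test_unmapped_item_rejected(self, tiny_likert):
        with pytest.raises(ConfigurationError):
            LikertDataset(
                scores=tiny_likert.scores,
                construct_map={"q1": "quality"},
                site=tiny_likert.site,
            )

    def test_descriptives_match_column_stats(self, tiny_likert):
        desc = descriptives(tiny_likert)
        assert desc.loc["q1", "mean"] == pytest.approx(tiny_likert.scores["q1"].mean())
        assert desc.loc["q1", "sd"] == pytest.approx(
            tiny_likert.scores["q1"].std(ddof=1)
        )
        assert desc.loc["q1", "min"] == 2 and desc.loc["q1", "max"] == 5


@given(shift=st.integers(-2, 2))
@settings(deadline=None, derandomize=True, max_examples=10)
def test_alpha_shift_invariance_property(shift):
    rng = np.random.default_rng(20)
    x = pd.DataFrame(rng.integers(1, 6, size=(30, 3)), columns=list("abc"))
    assert cronbach_alpha(x + shift) == pytest.approx(cronbach_alpha(x))
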