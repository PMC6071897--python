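"""Transition matrices, persistence measures, composites, weighted summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adipersist import reference
from adipersist.persistence import (
    PersistenceAnalyzer,
    PersistenceReport,
    QUINTILES,
    change_rates_by_category,
    compare_composites,
    composite_probabilities,
    neighboring_set,
    persistence_summary,
    population_weighted_probability,
    pro_rata_rate,
    round_half_up,
    transition_matrix,
)


class TestProRata:
    def test_published_annualization(self):
        # 27.2% over 14 months -> 23.3% per year
        assert round(pro_rata_rate(0.272, 14), 3) == 0.233

    def test_twelve_month_identity(self):
        assert pro_rata_rate(0.31, 12) == pytest.approx(0.31)

    def test_zero_rate(self):
        assert pro_rata_rate(0.0, 7) == 0.0

    def test_monotone_decreasing_in_window(self):
        rates = [pro_rata_rate(0.25, w) for w in (6, 12, 14, 24, 36)]
        assert all(a > b for a, b in zip(rates, rates[1:]))

    def test_invalid_window_errors(self):
        with pytest.raises(ValueError):
            pro_rata_rate(0.2, 0)


class TestNeighboringSet:
    @pytest.mark.parametrize(
        "q,expected",
        [(1, {1, 2, 3}), (2, {1, 2, 3}), (3, {2, 3, 4}), (4, {3, 4, 5}), (5, {3, 4, 5})],
    )
    def test_edge_quintiles_reach_two_inward(self, q, expected):
        assert neighboring_set(q) == expected

    def test_outside_set_always_has_two_quintiles(self):
        for q in QUINTILES:
            assert len(set(QUINTILES) - neighboring_set(q)) == 2

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            neighboring_set(0)


class TestTransitionMatrix:
    def test_hand_counted_row(self):
        # 4 movers from q1 to (1,1,2,4) -> (0.5, 0.25, 0, 0.25, 0)
        mat, counts = transition_matrix([1, 1, 1, 1], [1, 1, 2, 4])
        np.testing.assert_allclose(mat.loc[1], [0.5, 0.25, 0.0, 0.25, 0.0])
        assert counts[1] == 4

    def test_stayers_only_gives_identity(self):
        origins = [1, 2, 3, 4, 5] * 3
        mat, _ = transition_matrix(origins, origins)
        np.testing.assert_allclose(mat.to_numpy(), np.eye(5))

    def test_rows_sum_to_one_and_empty_rows_nan(self):
        mat, counts = transition_matrix([1, 1, 2], [3, 5, 2])
        sums = mat.sum(axis=1, skipna=False)
        np.testing.assert_allclose(sums.loc[[1, 2]], 1.0, atol=1e-9)
        assert mat.loc[3].isna().all() and counts[3] == 0

    def test_invalid_quintile_errors(self):
        with pytest.raises(ValueError, match="1..5"):
            transition_matrix([1, 6], [2, 2])


class TestPersistenceSummary:
    def test_identity_matrix_means_full_persistence(self):
        mat = pd.DataFrame(np.eye(5), index=list(QUINTILES), columns=list(QUINTILES))
        B, D = persistence_summary(mat)
        np.testing.assert_allclose(B, 0.0)
        np.testing.assert_allclose(D, 0.0)

    def test_q1_row_consistent_with_published_column(self):
        # a q1 destination row consistent with the published B=0.45, D=0.14
        rows = np.full((5, 5), 0.2)
        rows[0] = [0.55, 0.25, 0.06, 0.07, 0.07]
        mat = pd.DataFrame(rows, index=list(QUINTILES), columns=list(QUINTILES))
        B, D = persistence_summary(mat)
        assert B[1] == pytest.approx(0.45)
        assert D[1] == pytest.approx(0.14)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_d_never_exceeds_b_on_random_stochastic_matrices(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.dirichlet(np.ones(5), size=5)
        mat = pd.DataFrame(m, index=list(QUINTILES), columns=list(QUINTILES))
        B, D = persistence_summary(mat)
        assert ((D <= B + 1e-12) & (B <= 1.0) & (D >= -1e-12)).all()


class TestComposites:
    def test_published_cells(self):
        AB, AD = composite_probabilities(
            reference.PERSISTENCE_A, reference.PERSISTENCE_B, reference.PERSISTENCE_D
        )
        assert round_half_up(AB[4], 2) == 0.13  # A5 x B5 = 0.22 x 0.57
        assert round_half_up(AD[0], 2) == 0.02  # A1 x D1 = 0.15 x 0.14

    def test_zero_rate_zeroes_composites(self):
        AB, AD = composite_probabilities([0] * 5, [0.5] * 5, [0.2] * 5)
        assert not AB.any() and not AD.any()

    def test_bounds_chain(self):
        rng = np.random.default_rng(1)
        A, B = rng.uniform(size=5), rng.uniform(size=5)
        D = B * rng.uniform(size=5)  # D <= B by construction
        AB, AD = composite_probabilities(A, B, D)
        assert (AD <= AB + 1e-12).all() and (AB <= A + 1e-12).all() and (AD >= 0).all()

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            composite_probabilities([1.2] * 5, [0.5] * 5, [0.2] * 5)


class TestWeightedProbability:
    def test_published_headline_scalars(self):
        w_same = population_weighted_probability(
            reference.QUINTILE_SHARES, reference.PERSISTENCE_AB_PRINTED
        )
        w_near = population_weighted_probability(
            reference.QUINTILE_SHARES, reference.PERSISTENCE_AD_PRINTED
        )
        assert round(w_same * 100) == 10
        assert round(w_near * 100) == 4

    def test_equal_shares_equal_values_identity(self):
        assert population_weighted_probability([0.2] * 5, [0.37] * 5) == pytest.approx(0.37)

    def test_bad_share_sum_errors(self):
        with pytest.raises(ValueError, match="sum to 1"):
            population_weighted_probability([0.3, 0.3, 0.3, 0.3, 0.3], [0.1] * 5)

    def test_nan_values_dropped_with_renormalization(self, caplog):
        v = [0.1, np.nan, 0.1, 0.1, 0.1]
        out = population_weighted_probability([0.2] * 5, v)
        assert out == pytest.approx(0.1)


class TestChangeRates:
    def test_two_level_hand_count(self):
        cohort = pd.DataFrame(
            {
                "sex": ["male"] * 3 + ["female"],
                "changed_address": [True, False, False, True],
            }
        )
        t = change_rates_by_category(cohort, "sex").set_index("level")
        assert t.loc["male", "observed_change_probability"] == pytest.approx(1 / 3)
        assert t.loc["female", "observed_change_probability"] == pytest.approx(1.0)
        assert t.loc["male", "share"] == pytest.approx(0.75)

    def test_no_movers_gives_zero_everywhere(self):
        cohort = pd.DataFrame({"sex": ["male", "female"], "changed_address": [False, False]})
        t = change_rates_by_category(cohort, "sex")
        assert (t["observed_change_probability"] == 0).all()

    def test_unknown_factor_errors(self):
        with pytest.raises(ValueError, match="unknown factor"):
            change_rates_by_category(pd.DataFrame(), "shoe_size")

    def test_overall_rate_is_share_weighted_mean_of_levels(self, small_cohort):
        for factor in ("sex", "marital_status", "adi_quintile"):
            t = change_rates_by_category(small_cohort, factor)
            overall = (t["share"] * t["observed_change_probability"]).sum()
            assert overall == pytest.approx(small_cohort["changed_address"].mean())

    def test_quintile_rates_increase_with_deprivation(self, small_cohort):
        t = change_rates_by_category(small_cohort, "adi_quintile").set_index("level")
        rates = t["observed_change_probability"].loc[list(QUINTILES)].to_numpy()
        assert (np.diff(rates) > 0).all()


class TestReportAndFlags:
    def test_report_invariants(self):
        rep = PersistenceReport(
            A=reference.PERSISTENCE_A,
            B=reference.PERSISTENCE_B,
            D=reference.PERSISTENCE_D,
            shares=reference.QUINTILE_SHARES / reference.QUINTILE_SHARES.sum(),
        )
        assert (rep.AD <= rep.AB + 1e-12).all()
        assert (rep.AB <= rep.A + 1e-12).all()
        frame = rep.to_frame()
        assert frame.shape == (5, 5)

    def test_published_composite_cells_match_except_q2_axb(self):
        flags = compare_composites(
            reference.PERSISTENCE_A,
            reference.PERSISTENCE_B,
            reference.PERSISTENCE_D,
            reference.PERSISTENCE_AB_PRINTED,
            reference.PERSISTENCE_AD_PRINTED,
        )
        mism = flags[~flags["match"]]
        assert len(mism) == 1
        row = mism.iloc[0]
        assert (row["measure"], row["quintile"]) == ("AxB", 2)
        assert (row["computed"], row["printed"]) == (0.08, 0.09)


def _enumerate_statistics(cohort):
    """Brute-force oracle: loop over patients, count everything by hand."""
    n = len(cohort)
    movers = [r for _, r in cohort.iterrows() if r["changed_address"]]
    per_q = {}
    for q in QUINTILES:
        rows = [r for _, r in cohort.iterrows() if r["adi_quintile"] == q]
        qmov = [r for r in rows if r["changed_address"]]
        stat = {"count": len(rows), "share": len(rows) / n if n else np.nan}
        stat["rate"] = len(qmov) / len(rows) if rows else np.nan
        if qmov:
            same = sum(1 for r in qmov if r["endpoint_quintile"] == q)
            near = sum(1 for r in qmov if r["endpoint_quintile"] in neighboring_set(q))
            stat["B"] = 1 - same / len(qmov)
            stat["D"] = 1 - near / len(qmov)
        per_q[q] = stat
    return per_q, len(movers)


class TestSmallCohortEnumerationOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pipeline_statistics_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 21))
        cohort = pd.DataFrame(
            {
                "adi_quintile": rng.integers(1, 6, size=n),
                "endpoint_quintile": rng.integers(1, 6, size=n),
                "changed_address": rng.random(n) < 0.5,
            }
        )
        cohort.loc[~cohort["changed_address"], "endpoint_quintile"] = cohort.loc[
            ~cohort["changed_address"], "adi_quintile"
        ]
        oracle, total_movers = _enumerate_statistics(cohort)

        t = change_rates_by_category(cohort, "adi_quintile").set_index("level")
        movers = cohort[cohort["changed_address"]]
        mat, counts = transition_matrix(movers["adi_quintile"], movers["endpoint_quintile"])
        B, D = persistence_summary(mat)

        assert counts.sum() == total_movers  # conservation
        for q in QUINTILES:
            st_ = oracle[q]
            if st_["count"]:
                assert t.loc[q, "count"] == st_["count"]
                assert t.loc[q, "observed_change_probability"] == pytest.approx(st_["rate"])
            if "B" in st_:
                assert B[q] == pytest.approx(st_["B"])
                assert D[q] == pytest.approx(st_["D"])


class TestAnalyzer:
    def test_fit_produces_consistent_report(self, small_cohort):
        an = PersistenceAnalyzer(window_months=14).fit(small_cohort)
        rep = an.report_
        # A is the pro-rata annualized per-quintile rate
        t = change_rates_by_category(small_cohort, "adi_quintile").set_index("level")
        expected_A = t["observed_change_probability"].loc[list(QUINTILES)] * 12 / 14
        np.testing.assert_allclose(rep.A, expected_A)
        sums = an.transition_matrix_.sum(axis=1)
        np.testing.assert_allclose(sums[an.mover_counts_ > 0], 1.0, atol=1e-9)

    def test_supplied_a_row_reproduces_published_table(self):
        cohort = pd.DataFrame(
            {
                "adi_quintile": [1, 2, 3, 4, 5] * 4,
                "endpoint_quintile": [1, 2, 3, 4, 5] * 4,
                "changed_address": [True, False, False, False] * 5,
            }
        )
        an = PersistenceAnalyzer(A=reference.PERSISTENCE_A).fit(cohort)
        np.testing.assert_allclose(an.report_.A, reference.PERSISTENCE_A)
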