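import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from condmap import (
    Condition,
    SimulationConfig,
    build_differential_table,
    call_significant,
    differential_scores,
    estimate_fdr,
    generate_screen,
    mean_scores,
    merge_concentrations,
    standardize,
    static_threshold_calls,
)
from condmap.differential_scoring import MeanScoreMatrix
from condmap.errors import (
    ConfigurationError,
    DegenerateSpreadError,
    InsufficientDataError,
)
from condmap.types import make_tensor


def _means(rows):
    """rows: (query, array, drug, S) -> MeanScoreMatrix with n_reps=6."""
    df = pd.DataFrame(rows, columns=["query", "array", "drug", "S"])
    df["n_reps"] = 6
    return MeanScoreMatrix(df)


class TestMergeConcentrations:
    def test_two_concentrations_pool_replicates(self):
        rows = [
            ("Q", "A", "CPT", "10ug", r, s) for r, s in enumerate([1, 2, 3], 1)
        ] + [
            ("Q", "A", "CPT", "15ug", r, s) for r, s in enumerate([3, 4, 5], 1)
        ] + [("Q", "A", "UNT", "ctrl1", 1, 0.0)]
        merged = merge_concentrations(make_tensor(rows))
        assert merged.replicates("Q", "A", Condition("CPT")) == [1, 2, 3, 3, 4, 5]

    def test_single_concentration_unchanged_scores(self):
        rows = [("Q", "A", "HU", "50mM", r, float(r)) for r in (1, 2, 3)]
        rows += [("Q", "A", "UNT", "ctrl1", 1, 0.0)]
        merged = merge_concentrations(make_tensor(rows))
        assert merged.replicates("Q", "A", Condition("HU")) == [1.0, 2.0, 3.0]

    def test_paper_design_yields_six_replicates(self):
        cfg = SimulationConfig(n_queries=1, n_arrays=5, planted_fraction=0.0, seed=0)
        tensor, _ = generate_screen(cfg)
        merged = merge_concentrations(tensor)
        counts = merged.data.groupby(["query", "array", "drug"])["replicate"].agg(
            ["count", "max"]
        )
        assert (counts["count"] == 6).all()
        assert (counts["max"] == 6).all()  # contiguous from 1

    def test_missing_cells_contribute_only_present_replicates(self):
        rows = [
            ("Q", "A", "MMS", "lo", 1, 1.0),
            ("Q", "A", "MMS", "lo", 2, np.nan),
            ("Q", "A", "MMS", "hi", 1, 5.0),
            ("Q", "A", "UNT", "ctrl1", 1, 0.0),
        ]
        merged = merge_concentrations(make_tensor(rows))
        assert sorted(merged.replicates("Q", "A", Condition("MMS"))) == [1.0, 5.0]


class TestMeanScores:
    def test_six_replicate_mean(self):
        rows = [("Q", "A", "CPT", None, r, s) for r, s in enumerate([1, 2, 3, 3, 4, 5], 1)]
        m = mean_scores(make_tensor(rows))
        cell = m.data.iloc[0]
        assert cell["S"] == 3.0 and cell["n_reps"] == 6

    def test_missing_replicates_excluded_from_mean(self):
        rows = [
            ("Q", "A", "CPT", None, 1, 2.0),
            ("Q", "A", "CPT", None, 2, np.nan),
            ("Q", "A", "CPT", None, 3, 4.0),
        ]
        m = mean_scores(make_tensor(rows))
        cell = m.data.iloc[0]
        assert cell["S"] == 3.0 and cell["n_reps"] == 2

    def test_all_missing_cell_absent(self):
        rows = [
            ("Q", "A", "CPT", None, 1, np.nan),
            ("Q", "B", "CPT", None, 1, 1.0),
        ]
        m = mean_scores(make_tensor(rows))
        assert list(m.data["array"]) == ["B"]


class TestDifferentialScores:
    def test_simple_subtraction(self):
        m = _means([("Q", "A", "CPT", 2.5), ("Q", "A", "UNT", 0.5)])
        d = differential_scores(m, "Q", "CPT")
        assert d["A"] == pytest.approx(2.0)

    def test_missing_operand_gives_missing_d(self):
        m = _means([("Q", "A", "UNT", 0.5), ("Q", "B", "CPT", 1.0), ("Q", "B", "UNT", 0.0)])
        d = differential_scores(m, "Q", "CPT")
        assert np.isnan(d["A"]) and d["B"] == 1.0

    def test_equal_profiles_give_zero(self):
        rows = [("Q", a, "CPT", v) for a, v in [("A", 1.0), ("B", -2.0)]]
        rows += [("Q", a, "UNT", v) for a, v in [("A", 1.0), ("B", -2.0)]]
        d = differential_scores(_means(rows), "Q", "CPT")
        assert (d == 0).all()

    def test_absent_untreated_row_is_error(self):
        m = _means([("Q", "A", "CPT", 1.0)])
        with pytest.raises(ConfigurationError):
            differential_scores(m, "Q", "CPT")


class TestStandardize:
    def test_symmetric_unit_case(self):
        np.testing.assert_allclose(standardize([-1, 0, 1]), [-1, 0, 1])

    def test_frozen_four_point_case(self):
        # mean 5, sample sd sqrt(20/3)
        z = standardize([2, 4, 6, 8])
        np.testing.assert_allclose(
            z, [-1.161895, -0.387298, 0.387298, 1.161895], atol=1e-6
        )

    def test_constant_vector_is_error(self):
        with pytest.raises(DegenerateSpreadError):
            standardize([3.0, 3.0, 3.0, 3.0])

    def test_too_few_values_is_error(self):
        with pytest.raises(InsufficientDataError):
            standardize([1.0, 2.0])

    def test_missing_values_pass_through(self):
        z = standardize([1.0, np.nan, 2.0, 3.0])
        assert np.isnan(z[1])
        assert np.isfinite(z[[0, 2, 3]]).all()

    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=3, max_size=50,
        ).filter(lambda xs: np.std(xs) > 1e-9)
    )
    @settings(max_examples=200, deadline=None)
    def test_output_has_mean_zero_sd_one(self, xs):
        z = standardize(xs)
        assert abs(z.mean()) < 1e-10
        assert abs(z.std(ddof=1) - 1) < 1e-10


class TestEstimateFdr:
    def test_single_zero_z_theoretical(self):
        p, q = estimate_fdr([0.0], method="theoretical-null")
        assert p[0] == pytest.approx(1.0) and q[0] == pytest.approx(1.0)

    def test_bh_controls_null_fraction(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(10_000)
        p, q = estimate_fdr(z, method="theoretical-null")
        frac = (q < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / z.size)
        assert frac <= 0.05 + 3 * se

    def test_empirical_null_location_scale_invariance(self):
        # q-values from the empirical null on an affinely transformed vector
        # match theoretical-null q-values on the robustly restandardized one
        rng = np.random.default_rng(2)
        z = rng.standard_normal(2000)
        mu = np.median(z)
        sig = 1.4826 * np.median(np.abs(z - mu))
        z_pre = (z - mu) / sig
        _, q_theo = estimate_fdr(z_pre, method="theoretical-null")
        _, q_emp = estimate_fdr(2.0 + 3.0 * z, method="empirical-null")
        np.testing.assert_allclose(q_emp, q_theo, atol=1e-6)

    def test_degenerate_null_is_error(self):
        with pytest.raises(DegenerateSpreadError):
            estimate_fdr(np.zeros(100), method="empirical-null")

    def test_empirical_needs_enough_values(self):
        with pytest.raises(InsufficientDataError):
            estimate_fdr(np.arange(10.0), method="empirical-null")


def brute_force_bh(p):
    """Literal step-up: q_(i) = min_{j>=i} m p_(j) / j, order-preserving."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_i, i in enumerate(order, start=1):
        q[i] = min(
            min(m * p[j] / rank_j for rank_j, j in enumerate(order, start=1)
                if rank_j >= rank_i),
            1.0,
        )
    return q


class TestBenjaminiOracle:
    def test_matches_brute_force_on_1000_random_vectors(self):
        from condmap import benjamini_adjust

        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(1, 25))
            p = rng.random(n)
            np.testing.assert_allclose(
                benjamini_adjust(p), brute_force_bh(list(p)), rtol=0, atol=1e-13
            )

    def test_q_monotone_in_p(self):
        from condmap import benjamini_adjust

        rng = np.random.default_rng(5)
        p = rng.random(200)
        q = benjamini_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestCallSignificant:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["query", "array", "drug", "S_drug", "S_unt", "D", "Z", "p", "q"]
        )

    def test_below_threshold_negative_call(self):
        t = self._table([("Q", "A", "CPT", -3, 0, -3.0, -4, 1e-5, 0.049)])
        calls = call_significant(t)
        assert len(calls) == 1 and calls[0].direction == "negative"

    def test_exactly_alpha_not_called(self):
        t = self._table([("Q", "A", "CPT", 3, 0, 3.0, 4, 1e-5, 0.05)])
        assert call_significant(t) == []

    def test_empty_table(self):
        assert call_significant(self._table([])) == []

    def test_zero_d_never_called(self):
        t = self._table([("Q", "A", "CPT", 1, 1, 0.0, 0.0, 1e-9, 1e-9)])
        assert call_significant(t) == []


class TestStaticThresholds:
    def _m(self, s):
        return _means([("Q", "A", "UNT", s)])

    def test_below_lower_threshold_negative(self):
        out = static_threshold_calls(self._m(-2.5))
        assert list(out["direction"]) == ["negative"]

    def test_exactly_upper_threshold_not_called(self):
        assert static_threshold_calls(self._m(2.0)).empty

    def test_zero_score_not_called(self):
        assert static_threshold_calls(self._m(0.0)).empty

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ConfigurationError):
            static_threshold_calls(self._m(0.0), lo=2.0, hi=-2.4)


class TestPipelineEquivariance:
    def _screen_means(self):
        cfg = SimulationConfig(n_queries=2, n_arrays=120, planted_fraction=0.02, seed=13)
        tensor, _ = generate_screen(cfg)
        return mean_scores(merge_concentrations(tensor))

    def test_shift_both_rows_leaves_z_p_q_unchanged(self):
        means = self._screen_means()
        t0 = build_differential_table(means, null_method="theoretical-null")
        shifted = MeanScoreMatrix(means.data.copy())
        mask = shifted.data["query"] == "Q01"
        shifted.data.loc[mask, "S"] += 5.0  # both drug and UNT rows
        t1 = build_differential_table(shifted, null_method="theoretical-null")
        for col in ["Z", "p", "q"]:
            np.testing.assert_allclose(t0[col], t1[col], atol=1e-9)

    def test_shift_untreated_alone_shifts_d_not_z(self):
        means = self._screen_means()
        t0 = build_differential_table(means, null_method="theoretical-null")
        shifted = MeanScoreMatrix(means.data.copy())
        mask = (shifted.data["query"] == "Q01") & (shifted.data["drug"] == "UNT")
        shifted.data.loc[mask, "S"] += 5.0
        t1 = build_differential_table(shifted, null_method="theoretical-null")
        q1 = t1["query"] == "Q01"
        np.testing.assert_allclose(
            t1.loc[q1, "D"], t0.loc[q1, "D"] - 5.0, atol=1e-9
        )
        np.testing.assert_allclose(t1["Z"], t0["Z"], atol=1e-9)

    def test_null_screen_call_rate_controlled(self):
        cfg = SimulationConfig(n_queries=3, n_arrays=400, planted_fraction=0.0, seed=17)
        tensor, _ = generate_screen(cfg)
        table = build_differential_table(mean_scores(merge_concentrations(tensor)))
        calls = call_significant(table, alpha=0.05)
        n = len(table)
        assert len(calls) <= 0.05 * n + 3 * np.sqrt(n * 0.05 * 0.95)
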