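"""Robust factorial statistics: trimmed means, Wilcox-type two-way ANOVA,
noncentral-t power analysis, descriptives and stage frequencies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from jointqmri.biostats import (
    descriptive_summary,
    effect_size_from_power,
    power_two_sample_t,
    stage_frequency_table,
    trimmed_mean_stats,
    trimmed_two_way_anova,
)
from jointqmri.grids import DegenerateDataError, ParameterError, ScoreRecord
from jointqmri.nifti_io import ha_concentration_table
from jointqmri.phantoms import ScoreSimSpec, make_ordinal_score_dataset


def brute_force_trimmed(x, trim):
    """Independent oracle: sort, slice, winsorize, average."""
    xs = sorted(x)
    n = len(xs)
    g = int(np.floor(trim * n))
    core = xs[g : n - g]
    tmean = sum(core) / len(core)
    wins = [min(max(v, xs[g]), xs[n - g - 1]) for v in xs]
    mw = sum(wins) / n
    wvar = sum((v - mw) ** 2 for v in wins) / (n - 1)
    return tmean, wvar, n - 2 * g


def null_frame(rng, n_per_cell=6):
    rows = []
    for a in ("CTR", "CGH", "CGH-NC"):
        for b in (24, 56, 84):
            for v in rng.normal(size=n_per_cell):
                rows.append({"group": a, "time_days": b, "value": v})
    return pd.DataFrame(rows)


class TestTrimmedMeanStats:
    def test_order_statistics_arithmetic(self):
        st_ = trimmed_mean_stats(range(1, 11), trim=0.2)
        assert st_.trimmed_mean == pytest.approx(5.5)  # mean of {3..8}
        assert st_.h == 6

    def test_trim_zero_reduces_to_classical(self, rng):
        x = rng.normal(size=17)
        st_ = trimmed_mean_stats(x, trim=0.0)
        assert st_.trimmed_mean == pytest.approx(x.mean())
        assert st_.winsorized_variance == pytest.approx(x.var(ddof=1))
        assert st_.h == 17

    def test_agrees_with_brute_force_oracle(self, rng):
        for n in (5, 8, 11, 20):
            for trim in (0.0, 0.1, 0.2, 0.25):
                x = rng.normal(size=n) * 10
                mine = trimmed_mean_stats(x, trim)
                oracle = brute_force_trimmed(x, trim)
                assert mine.trimmed_mean == pytest.approx(oracle[0], rel=1e-12)
                assert mine.winsorized_variance == pytest.approx(oracle[1], rel=1e-12)
                assert mine.h == oracle[2]

    def test_empty_input_errors(self):
        with pytest.raises(ParameterError):
            trimmed_mean_stats([])


class TestTrimmedTwoWayAnova:
    def test_zero_variance_cells_error_not_silent_zero(self):
        df = null_frame(np.random.default_rng(0))
        df["value"] = 7.0
        with pytest.raises(DegenerateDataError):
            trimmed_two_way_anova(df)

    def test_single_level_factor_errors(self):
        df = null_frame(np.random.default_rng(0))
        with pytest.raises(ParameterError):
            trimmed_two_way_anova(df[df["group"] == "CTR"])

    def test_empty_cell_error_names_cell(self, rng):
        df = null_frame(rng)
        df = df[~((df["group"] == "CGH") & (df["time_days"] == 56))]
        with pytest.raises(ParameterError, match="CGH"):
            trimmed_two_way_anova(df)

    def test_null_type_one_error_calibrated(self, rng):
        # Monte-Carlo: rejection rate at alpha=0.05 under the null (3x3, n=6)
        reps = 600
        rej = {"A": 0, "B": 0, "AB": 0}
        for _ in range(reps):
            res = trimmed_two_way_anova(null_frame(rng))
            rej["A"] += res.p_a < 0.05
            rej["B"] += res.p_b < 0.05
            rej["AB"] += res.p_ab < 0.05
        for k, v in rej.items():
            assert 0.02 <= v / reps <= 0.09, (k, v / reps)

    def test_planted_main_effect_detected(self, rng):
        # strong group effect d=1.5: power for factor A should be high
        hits = 0
        reps = 120
        for _ in range(reps):
            df = null_frame(rng)
            df.loc[df["group"] == "CGH-NC", "value"] += 1.5
            hits += trimmed_two_way_anova(df).p_a < 0.05
        assert hits / reps >= 0.8

    def test_trim_zero_matches_independent_welch_johansen_oracle(self, rng):
        # with trim=0 the statistic uses plain means and variances; compare
        # against an independently coded Johansen quadratic form
        df = null_frame(rng, n_per_cell=8)
        res = trimmed_two_way_anova(df, trim=0.0)

        means, var_over_n = [], []
        for a in ("CTR", "CGH", "CGH-NC"):
            for b in (24, 56, 84):
                x = df[(df["group"] == a) & (df["time_days"] == b)]["value"].to_numpy()
                means.append(x.mean())
                var_over_n.append(x.var(ddof=1) / len(x))
        V = np.diag(var_over_n)
        cj = np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])
        CA = np.kron(cj, np.ones((1, 3)))
        m = np.asarray(means)
        q_oracle = m @ CA.T @ np.linalg.inv(CA @ V @ CA.T) @ CA @ m
        assert res.q_a == pytest.approx(q_oracle, rel=1e-10)

    def test_bootstrap_p_agrees_roughly_with_analytic(self, rng):
        df = null_frame(rng)
        df.loc[df["group"] == "CGH-NC", "value"] += 2.0
        a = trimmed_two_way_anova(df)
        b = trimmed_two_way_anova(df, n_boot=400, seed=1)
        # both should call the planted effect significant
        assert a.p_a < 0.05 and b.p_a < 0.05

    def test_accepts_score_records(self):
        recs = make_ordinal_score_dataset(ScoreSimSpec(noise="normal", seed=3))
        res = trimmed_two_way_anova(recs)
        assert 0 <= res.p_a <= 1 and 0 <= res.p_ab <= 1


class TestPower:
    def test_zero_effect_power_equals_alpha(self):
        assert power_two_sample_t(12, 0.0, 0.05) == pytest.approx(0.05, abs=1e-9)

    def test_large_effect_power_approaches_one(self):
        assert power_two_sample_t(12, 5.0, 0.05) > 0.999

    def test_monte_carlo_oracle(self, rng):
        # simulate the two-sample t test directly (10^5 replicates)
        n, d, alpha = 12, 1.2, 0.05
        reps = 100_000
        x = rng.normal(d, 1.0, (reps, n))
        y = rng.normal(0.0, 1.0, (reps, n))
        sp = np.sqrt((x.var(axis=1, ddof=1) + y.var(axis=1, ddof=1)) / 2)
        t = (x.mean(axis=1) - y.mean(axis=1)) / (sp * np.sqrt(2 / n))
        from scipy import stats

        tc = stats.t.ppf(1 - alpha / 2, 2 * n - 2)
        mc_power = (np.abs(t) > tc).mean()
        assert power_two_sample_t(n, d, alpha) == pytest.approx(mc_power, abs=0.005)

    def test_effect_size_study_design_value(self):
        # n=12 per group, alpha=0.05, power=0.8, two-sided
        d = effect_size_from_power(12, 0.05, 0.8)
        assert round(d, 1) == 1.2  # two significant figures

    def test_inverse_consistency(self):
        for n in (5, 12, 30):
            for target in (0.5, 0.8, 0.95):
                d = effect_size_from_power(n, 0.05, target)
                assert power_two_sample_t(n, d, 0.05) == pytest.approx(target, abs=1e-6)

    def test_power_just_above_alpha_needs_tiny_effect(self):
        d = effect_size_from_power(12, 0.05, 0.0501)
        assert d < 0.05

    def test_invalid_alpha_errors(self):
        with pytest.raises(ParameterError):
            power_two_sample_t(12, 1.0, alpha=1.5)


class TestDescriptives:
    def test_basic_order_statistics(self):
        s = descriptive_summary([1, 2, 3, 4, 5])
        assert s["median"] == 3 and s["min"] == 1 and s["max"] == 5

    def test_singleton(self):
        s = descriptive_summary([7.0])
        assert s["median"] == s["min"] == s["max"] == 7.0 and s["iqr"] == 0.0

    def test_ha_fixture_group_row(self):
        # packaged synovial-fluid HA concentrations: CGH-NC row
        tab = ha_concentration_table()
        row = tab[tab["group"] == "CGH-NC"]["ha_ng_ml"]
        assert sorted(row) == [68.57, 90.66, 119.62]
        assert descriptive_summary(row)["median"] == pytest.approx(90.66)


class TestStageFrequencies:
    def test_single_record(self):
        t = stage_frequency_table([ScoreRecord("s", "CTR", 24, "score", 2.0)], "score")
        assert t.loc[2, ("CTR", 24)] == 1

    def test_counts_conserved_per_cell(self):
        recs = make_ordinal_score_dataset(ScoreSimSpec(noise="ordinalized", seed=8))
        t = stage_frequency_table(recs, "score")
        assert (t.sum(axis=0) == 6).all()
        assert t.to_numpy().sum() == len(recs)

    def test_normalized_columns_sum_to_one(self):
        recs = make_ordinal_score_dataset(ScoreSimSpec(noise="ordinalized", seed=8))
        t = stage_frequency_table(recs, "score", normalize=True)
        np.testing.assert_allclose(t.sum(axis=0), 1.0)

    def test_non_ordinal_variable_errors(self):
        recs = make_ordinal_score_dataset(ScoreSimSpec(noise="normal", seed=8))
        with pytest.raises(ParameterError):
            stage_frequency_table(recs, "score")

    def test_planted_monotone_time_effect_moves_modal_stage(self):
        ok = 0
        n_seeds = 40
        for seed in range(n_seeds):
            effects = {(g, t): {24: 0.0, 56: 1.5, 84: 3.0}[t]
                       for g in ("CTR", "CGH", "CGH-NC") for t in (24, 56, 84)}
            recs = make_ordinal_score_dataset(
                ScoreSimSpec(cell_effects=effects, noise="ordinalized", seed=seed)
            )
            t = stage_frequency_table(recs, "score")
            modal = [t[("CTR", d)].idxmax() for d in (24, 56, 84)]
            ok += modal == sorted(modal)
        assert ok >= 0.9 * n_seeds


@given(st.lists(st.floats(-1e6, 1e6), min_size=5, max_size=40), st.sampled_from([0.0, 0.1, 0.2]))
def test_trimmed_stats_brute_force_property(xs, trim):
    mine = trimmed_mean_stats(xs, trim)
    oracle = brute_force_trimmed(xs, trim)
    assert mine.trimmed_mean == pytest.approx(oracle[0], rel=1e-9, abs=1e-9)
    assert mine.winsorized_variance == pytest.approx(oracle[1], rel=1e-9, abs=1e-9)
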