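import numpy as np
import pandas as pd
import pytest

import surveysim as ss
from surveysim.stratified import _error_metrics, _nearest_populated


def _mini_setdet(ns, catches):
    return pd.DataFrame({"sim": 1, "year": 1, "division": 1, "strat": 1,
                         "set": np.arange(1, ns + 1), "n": catches})


class TestScaleLengthFrequencies:
    def test_all_measured_identity(self):
        setdet = _mini_setdet(1, [3])
        samp = pd.DataFrame({"sim": 1, "year": 1, "set": 1, "fish": [1, 2, 3],
                             "age": 1, "length": [3.0, 3.0, 6.0],
                             "measured": True, "aged": False})
        out = ss.scale_length_frequencies(samp, setdet, 3.0)
        got = out.set_index("length_bin")["n_l"]
        assert got[3.0] == 2 and got[6.0] == 1

    def test_scaling_ratio(self):
        # 10 measured in a bin, 50 of 100 measured -> 20
        setdet = _mini_setdet(1, [100])
        lengths = np.r_[np.full(10, 3.0), np.full(40, 6.0)]
        samp = pd.DataFrame({"sim": 1, "year": 1, "set": 1,
                             "fish": np.arange(50), "age": 1,
                             "length": lengths, "measured": True, "aged": False})
        out = ss.scale_length_frequencies(samp, setdet, 3.0)
        got = out.set_index("length_bin")["n_l"]
        assert got[3.0] == pytest.approx(20.0)
        assert out["n_l"].sum() == pytest.approx(100.0)

    def test_zero_catch_set_retained(self):
        setdet = _mini_setdet(2, [3, 0])
        samp = pd.DataFrame({"sim": 1, "year": 1, "set": 1, "fish": [1, 2, 3],
                             "age": 1, "length": 3.0, "measured": True,
                             "aged": False})
        out = ss.scale_length_frequencies(samp, setdet, 3.0)
        assert set(out["set"]) == {1, 2}
        assert out.loc[out["set"] == 2, "n_l"].sum() == 0

    def test_catch_without_measurement_raises(self):
        setdet = _mini_setdet(1, [5])
        samp = pd.DataFrame({"sim": [1], "year": [1], "set": [1], "fish": [1],
                             "age": [1], "length": [3.0], "measured": [False],
                             "aged": [False]})
        with pytest.raises(ValueError, match="measured"):
            ss.scale_length_frequencies(samp, setdet, 3.0)


class TestBuildApplyAlk:
    def test_counting_proportions(self):
        setdet = _mini_setdet(1, [3])
        samp = pd.DataFrame({"sim": 1, "year": 1, "set": 1, "fish": [1, 2, 3],
                             "age": [3, 3, 4], "length": [25.0, 26.0, 27.0],
                             "measured": True, "aged": True})
        alk = ss.build_alk(samp, setdet, "division", 3.0)
        p = alk.set_index("age")["p"]
        assert p[3] == pytest.approx(2 / 3) and p[4] == pytest.approx(1 / 3)

    def test_single_fish_probability_one(self):
        setdet = _mini_setdet(1, [1])
        samp = pd.DataFrame({"sim": [1], "year": [1], "set": [1], "fish": [1],
                             "age": [5], "length": [40.0], "measured": [True],
                             "aged": [True]})
        alk = ss.build_alk(samp, setdet, "set", 3.0)
        assert alk["p"].iloc[0] == 1.0

    def test_columns_sum_to_one(self, small_survey):
        alk = ss.build_alk(small_survey.samp, small_survey.setdet,
                           "division", 3.0)
        sums = alk.groupby(["sim", "year", "unit", "length_bin"])["p"].sum()
        assert np.allclose(sums, 1.0)

    def test_apply_matrix_product(self):
        setdet = _mini_setdet(1, [20])
        samp = pd.DataFrame({"sim": 1, "year": 1, "set": 1, "fish": [1, 2],
                             "age": [3, 4], "length": [25.0, 26.0],
                             "measured": True, "aged": True})
        freq = pd.DataFrame({"sim": [1], "year": [1], "set": [1],
                             "length_bin": [27.0], "m_l": [2], "n_l": [20.0]})
        alk = ss.build_alk(samp, setdet, "division", 3.0)
        out = ss.apply_alk(freq, alk, setdet, "division")
        got = out.set_index("age")["n_a"]
        assert got[3] == pytest.approx(10.0) and got[4] == pytest.approx(10.0)

    def test_empty_bin_borrows_nearest_lower(self):
        setdet = _mini_setdet(1, [10])
        samp = pd.DataFrame({"sim": 1, "year": 1, "set": 1, "fish": [1, 2],
                             "age": [2, 6], "length": [10.0, 22.0],
                             "measured": True, "aged": True})
        # frequency in bin 18 (no aged fish); nearest populated are 12 and 24
        # at distances 2 and 2 bins -> tie resolved to the lower bin (12)
        freq = pd.DataFrame({"sim": [1], "year": [1], "set": [1],
                             "length_bin": [18.0], "m_l": [1], "n_l": [10.0]})
        alk = ss.build_alk(samp, setdet, "division", 3.0)
        out = ss.apply_alk(freq, alk, setdet, "division")
        assert out.set_index("age")["n_a"][2] == pytest.approx(10.0)

    def test_no_aged_fish_at_scale_raises(self):
        setdet = _mini_setdet(2, [5, 5])
        samp = pd.DataFrame({"sim": 1, "year": 1, "set": 1, "fish": [1],
                             "age": [3], "length": [25.0], "measured": True,
                             "aged": True})
        freq = pd.DataFrame({"sim": [1], "year": [1], "set": [2],
                             "length_bin": [27.0], "m_l": [1], "n_l": [5.0]})
        alk = ss.build_alk(samp, setdet, "set", 3.0)
        with pytest.raises(ValueError, match="no aged fish"):
            ss.apply_alk(freq, alk, setdet, "set")

    def test_degenerate_single_age_population(self, flat_grid):
        pop = ss.sim_abundance(ss.PopulationParams(
            ages=(4,), years=(1, 2), mu_r=225 * 64, sigma_r=0.0,
            mu_Z=np.log(2), sigma_delta=0.0, sigma_L=0.0), seed=2)
        sp = ss.distribute_population(pop, flat_grid,
                                      ss.FieldParams(sd=0, group_ages=None),
                                      ss.DepthPrefParams(50, 1e9), seed=2)
        sv = ss.sim_survey(sp, ss.SurveySpec(trawl_dim=(1.0, 0.5),
                                             q_table=(1.0,)), seed=2)
        est = ss.run_strat(sv, ss.StratOptions(alk_scale="set"))
        tot = est.total_strat.set_index("year")["I_hat"]
        age = est.age_strat.set_index("year")["I_hat"]
        assert np.allclose(age.to_numpy(), tot.to_numpy())


class TestStratifiedEstimate:
    def test_worked_example(self):
        per_set = pd.DataFrame({"sim": 1, "year": 1, "strat": 1,
                                "set": [1, 2], "value": [2.0, 4.0]})
        areas = pd.DataFrame({"division": [1], "strat": [1], "n_cells": [100],
                              "area": [100.0]})
        out = ss.stratified_estimate(per_set, areas, (1.0, 1.0))
        assert out["I_hat"].iloc[0] == pytest.approx(300.0)
        # N_h = 100, n_h = 2, s^2 = 2 -> 100^2 * 0.98 * 2 / 2
        assert out["var"].iloc[0] == pytest.approx(100 ** 2 * 0.98)

    def test_all_zero_catches(self):
        per_set = pd.DataFrame({"sim": 1, "year": 1, "strat": 1,
                                "set": [1, 2, 3], "value": 0.0})
        areas = pd.DataFrame({"division": [1], "strat": [1], "n_cells": [10],
                              "area": [10.0]})
        out = ss.stratified_estimate(per_set, areas, (1.0, 1.0))
        assert out["I_hat"].iloc[0] == 0.0 and out["var"].iloc[0] == 0.0

    def test_single_set_stratum_raises(self):
        per_set = pd.DataFrame({"sim": 1, "year": 1, "strat": [1, 1, 2],
                                "set": [1, 2, 3], "value": [1.0, 2.0, 3.0]})
        areas = pd.DataFrame({"division": [1, 1], "strat": [1, 2],
                              "n_cells": [10, 10], "area": [10.0, 10.0]})
        with pytest.raises(ValueError, match=r"\[2\]"):
            ss.stratified_estimate(per_set, areas, (1.0, 1.0))

    def test_census_fpc_zeroes_variance(self, tiny_spatial):
        spec = ss.SurveySpec(census=True, trawl_dim=(1.0, 1.0),
                             q_table=(1.0,) * 6, lengths_cap=10 ** 9,
                             ages_cap=10 ** 9, age_space_group="set")
        sv = ss.sim_survey(tiny_spatial, spec, seed=0)
        est = ss.run_strat(sv, ss.StratOptions(alk_scale="set"))
        assert np.allclose(est.total_strat["var"], 0.0)


class TestRunStrat:
    def test_length_marginal_equals_total(self, small_survey):
        est = ss.run_strat(small_survey)
        by_len = est.length_strat.groupby(["sim", "year"])["I_hat"].sum()
        tot = est.total_strat.set_index(["sim", "year"])["I_hat"]
        assert np.allclose(by_len.sort_index(), tot.sort_index(), rtol=1e-9)

    def test_age_marginal_equals_total(self, small_survey):
        est = ss.run_strat(small_survey)
        by_age = est.age_strat.groupby(["sim", "year"])["I_hat"].sum()
        tot = est.total_strat.set_index(["sim", "year"])["I_hat"]
        assert np.allclose(by_age.sort_index(), tot.sort_index(), rtol=1e-9)

    def test_options_echoed(self, small_survey):
        opts = ss.StratOptions(length_group=6.0, alk_scale="division")
        est = ss.run_strat(small_survey, opts)
        assert est.options == opts and est.length_group == 6.0

    def test_alk_scale_finer_than_age_sampling_raises(self, small_survey):
        # ageing was pooled at division scale, so stratum-level keys can be
        # empty: the analysis must refuse rather than silently drop abundance
        with pytest.raises(ValueError, match="no aged fish"):
            ss.run_strat(small_survey, ss.StratOptions(alk_scale="strat"))

    def test_engine_matches_composed_public_operations(self, reduced_spatial):
        """The vectorized analysis must equal the step-by-step table route."""
        spec = ss.SurveySpec(lengths_cap=30, ages_cap=5)
        sv = ss.sim_survey(reduced_spatial, spec, seed=21)
        est = ss.run_strat(sv, ss.StratOptions(alk_scale="division"))

        pop = reduced_spatial.population
        w = float(pop.params.length_group)
        freq = ss.scale_length_frequencies(sv.samp, sv.setdet, w)
        alk = ss.build_alk(sv.samp, sv.setdet, "division", w)
        n_ai = ss.apply_alk(freq, alk, sv.setdet, "division")
        areas = reduced_spatial.grid.strat_areas()

        # totals route
        per_set = sv.setdet.rename(columns={"n": "value"})[
            ["sim", "year", "strat", "set", "value"]].astype({"value": float})
        tot = ss.stratified_estimate(per_set, areas, spec.trawl_dim)
        merged = tot.merge(est.total_strat, on=["sim", "year"],
                           suffixes=("_ops", "_engine"))
        assert np.allclose(merged["I_hat_ops"], merged["I_hat_engine"], rtol=1e-9)
        assert np.allclose(merged["var_ops"], merged["var_engine"], rtol=1e-9)

        # at-age route for one age with substantial abundance
        age = pop.ages[4]
        base = sv.setdet[["sim", "year", "strat", "set"]].copy()
        vals = n_ai[n_ai["age"] == age]
        per_set_a = base.merge(vals, on=["sim", "year", "set"], how="left")
        per_set_a["value"] = per_set_a["n_a"].fillna(0.0)
        age_ops = ss.stratified_estimate(per_set_a, areas, spec.trawl_dim)
        age_engine = est.age_strat[est.age_strat["age"] == age]
        merged_a = age_ops.merge(age_engine, on=["sim", "year"],
                                 suffixes=("_ops", "_engine"))
        assert np.allclose(merged_a["I_hat_ops"], merged_a["I_hat_engine"],
                           rtol=1e-9)


class TestStratError:
    def test_perfect_estimates_zero_metrics(self, tiny_spatial):
        spec = ss.SurveySpec(census=True, trawl_dim=(1.0, 1.0),
                             q_table=(1.0,) * 6, lengths_cap=10 ** 9,
                             ages_cap=10 ** 9, age_space_group="set")
        sv = ss.sim_survey(tiny_spatial, spec, seed=0)
        err = ss.strat_error(ss.run_strat(sv, ss.StratOptions(alk_scale="set")), sv)
        for kind in ("total", "length", "age"):
            stats = getattr(err, f"{kind}_strat_error_stats")
            scale = tiny_spatial.population.N.sum()
            assert stats["RMSE"].iloc[0] / scale < 1e-12

    def test_plus_minus_one_errors(self):
        stats = _error_metrics(np.array([1.0, -1.0]))
        assert stats == {"ME": 0.0, "MAE": 1.0, "MSE": 1.0, "RMSE": 1.0}

    def test_metric_inequalities(self, small_survey):
        err = ss.strat_error(ss.run_strat(small_survey), small_survey)
        for kind in ("total", "length", "age"):
            s = getattr(err, f"{kind}_strat_error_stats").iloc[0]
            assert s["RMSE"] ** 2 == pytest.approx(s["MSE"])
            assert s["MSE"] >= s["ME"] ** 2 - 1e-9
            assert s["MAE"] >= abs(s["ME"]) - 1e-9
            assert s["RMSE"] >= abs(s["ME"]) - 1e-9

    def test_misaligned_years_raise(self, small_survey):
        est = ss.run_strat(small_survey)
        bad = est.total_strat.copy()
        bad["year"] = bad["year"] + 100
        broken = ss.StratEstimates(total_strat=bad,
                                   length_strat=est.length_strat,
                                   age_strat=est.age_strat,
                                   options=est.options,
                                   length_group=est.length_group)
        with pytest.raises(ValueError, match="align"):
            ss.strat_error(broken, small_survey)

    def test_coarser_analysis_bins_consistent(self, small_survey):
        est = ss.run_strat(small_survey, ss.StratOptions(length_group=6.0))
        err = ss.strat_error(est, small_survey)
        tot = err.total_strat_error
        by_len = (err.length_strat_error.groupby(["sim", "year"])
                  [["I_hat", "I"]].sum().reset_index())
        merged = by_len.merge(tot, on=["sim", "year"], suffixes=("_l", "_t"))
        assert np.allclose(merged["I_hat_l"], merged["I_hat_t"], rtol=1e-9)
        assert np.allclose(merged["I_l"], merged["I_t"], rtol=1e-6)


def test_nearest_populated_mapping():
    pop = np.array([[False, True, False, False, True],
                    [False, False, False, False, False]])
    out = _nearest_populated(pop)
    # index 3 is nearer the populated bin at 4 than the one at 1
    assert out[0].tolist() == [1, 1, 1, 4, 4]
    assert np.all(out[1] == -1)


def test_nearest_populated_tie_prefers_lower():
    pop = np.array([[True, False, True]])
    out = _nearest_populated(pop)
    assert out[0, 1] == 0
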