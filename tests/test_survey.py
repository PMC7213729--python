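import numpy as np
import pytest

import surveysim as ss
from surveysim._rng import substream
from surveysim.survey import _GridCache, _draw_sets


class TestCatchability:
    def test_logistic_anchors(self):
        assert ss.logistic_catchability(3.0, 2.0, 3.0) == pytest.approx(0.5)
        assert ss.logistic_catchability(5.0, 2.0, 3.0) == pytest.approx(
            1 / (1 + np.exp(-4)))

    def test_monotone_in_age(self):
        q = ss.logistic_catchability(np.arange(1, 21))
        assert np.all(np.diff(q) > 0)

    def test_custom_table_overrides_logistic(self, tiny_spatial):
        spec = ss.SurveySpec(q_table=(0.1,) * 6)
        q = spec.catchability(tiny_spatial.population.ages)
        assert np.allclose(q, 0.1)


class TestAllocation:
    def test_density_allocation_arithmetic(self, flat_grid):
        # A_strat = 225 km^2 at D = 2/225 -> 2 sets; floor keeps it at min_sets
        sets = ss.allocate_sets(flat_grid, set_den=2 / 225, min_sets=1, seed=0)
        assert len(sets) == 2

    def test_min_sets_floor(self, flat_grid):
        # 225 km^2 * 0.4/225 = 0.4 rounds to 0, floored to 2
        sets = ss.allocate_sets(flat_grid, set_den=0.4 / 225, min_sets=2, seed=0)
        assert len(sets) == 2

    def test_doubling_density_doubles_sets(self, reduced_grid):
        low = ss.allocate_sets(reduced_grid, set_den=20 / 1000, min_sets=1, seed=0)
        high = ss.allocate_sets(reduced_grid, set_den=40 / 1000, min_sets=1, seed=0)
        assert len(high) == pytest.approx(2 * len(low), rel=0.05)

    def test_sets_stay_in_their_stratum(self, reduced_grid):
        sets = ss.allocate_sets(reduced_grid, seed=3)
        cells = reduced_grid.cells.set_index("cell")
        assert (cells.loc[sets["cell"], "strat"].to_numpy()
                == sets["strat"].to_numpy()).all()

    def test_census_covers_every_cell_once(self, flat_grid):
        sets = ss.allocate_sets(flat_grid, census=True, seed=0)
        assert sorted(sets["cell"]) == sorted(flat_grid.cells["cell"])


class TestCatch:
    def test_census_returns_exact_cell_abundance(self, tiny_spatial):
        spec = ss.SurveySpec(census=True, trawl_dim=(1.0, 1.0),
                             q_table=(1.0,) * 6, lengths_cap=10 ** 9,
                             ages_cap=10 ** 9)
        sv = ss.sim_survey(tiny_spatial, spec, seed=0)
        per_year = sv.setdet.groupby("year")["n"].sum().to_numpy()
        assert np.allclose(per_year, tiny_spatial.population.N.sum(axis=0))

    def test_zero_cells_catch_nothing(self, flat_grid, default_pop):
        pop = ss.sim_abundance(ss.PopulationParams(
            ages=(1, 2), years=(1,), mu_r=1.0, sigma_r=0.0, mu_Z=5.0,
            sigma_delta=0.0), seed=0)
        sp = ss.distribute_population(pop, flat_grid,
                                      ss.FieldParams(sd=0, group_ages=None),
                                      ss.DepthPrefParams(50, 1e9), seed=0)
        sv = ss.sim_survey(sp, ss.SurveySpec(min_sets=2, trawl_dim=(1.0, 1.0)),
                           seed=0)
        assert sv.setdet["n"].sum() <= 1  # ~one fish in the whole sea

    def test_binomial_mean(self, flat_grid):
        # constant cell abundance; E[n] = N_cell * p * q
        pop = ss.sim_abundance(ss.PopulationParams(
            ages=(1,), years=(1,), mu_r=225 * 10_000, sigma_r=0.0, mu_Z=0.5,
            sigma_delta=0.0), seed=0)
        sp = ss.distribute_population(pop, flat_grid,
                                      ss.FieldParams(sd=0, group_ages=None),
                                      ss.DepthPrefParams(50, 1e9), seed=0)
        spec = ss.SurveySpec(trawl_dim=(0.3, 0.1), q_table=(0.5,),
                             set_den=20 / 225, min_sets=1)
        catches = []
        for i in range(400):
            sv = ss.sim_survey(sp, spec, seed=substream(1, "b", i))
            catches.append(sv.setdet["n"].mean())
        expected = 10_000 * (0.03 / 1.0) * 0.5  # 150 per set
        got = np.mean(catches)
        se = np.std(catches) / np.sqrt(len(catches))
        assert abs(got - expected) < 3 * se + 0.5

    def test_colocated_sets_never_exceed_cell_abundance(self, tiny_spatial):
        spec = ss.SurveySpec(trawl_dim=(1.0, 1.0), q_table=(1.0,) * 6,
                             set_den=100 / 225, min_sets=2)
        sv = ss.sim_survey(tiny_spatial, spec, seed=5)
        per_cell = sv.setdet.groupby(["year", "cell"])["n"].sum().reset_index()
        truth = tiny_spatial.abundance.sum(axis=0)  # (years, cells)
        years = tiny_spatial.population.years
        cells = tiny_spatial.grid.cells["cell"].to_numpy()
        cell_pos = {c: i for i, c in enumerate(cells)}
        for _, row in per_cell.iterrows():
            y = np.searchsorted(years, row["year"])
            assert row["n"] <= truth[y, cell_pos[row["cell"]]] + 1e-9

    def test_expected_catch_independent_of_colocation(self, flat_grid):
        # heavy co-location (small strata, many sets) must not bias mean catch
        pop = ss.sim_abundance(ss.PopulationParams(
            ages=(1,), years=(1,), mu_r=225 * 1000, sigma_r=0.0, mu_Z=0.5,
            sigma_delta=0.0), seed=0)
        sp = ss.distribute_population(pop, flat_grid,
                                      ss.FieldParams(sd=0, group_ages=None),
                                      ss.DepthPrefParams(50, 1e9), seed=0)
        spec = ss.SurveySpec(trawl_dim=(0.5, 0.2), q_table=(1.0,),
                             set_den=300 / 225, min_sets=1)
        means = [ss.sim_survey(sp, spec, seed=substream(2, "c", i))
                 .setdet["n"].mean() for i in range(200)]
        expected = 1000 * 0.1  # N_cell * A_trawl / A_cell
        se = np.std(means) / np.sqrt(len(means))
        assert np.mean(means) == pytest.approx(expected, abs=3 * se + 0.2)


class TestSampling:
    def test_fish_counts_match_set_totals(self, small_survey):
        per_set = small_survey.samp.groupby(["sim", "set"]).size()
        sd = small_survey.setdet.set_index(["sim", "set"])["n"]
        sd = sd[sd > 0]
        assert per_set.sort_index().equals(sd.sort_index().astype(per_set.dtype))

    def test_measured_cap_respected(self, reduced_spatial):
        spec = ss.SurveySpec(lengths_cap=5)
        sv = ss.sim_survey(reduced_spatial, spec, seed=2)
        meas = sv.samp[sv.samp["measured"]].groupby(["sim", "set"]).size()
        assert meas.max() <= 5
        caught = sv.samp.groupby(["sim", "set"]).size()
        small = caught[caught <= 5].index
        assert (meas.reindex(small).fillna(0) == caught.loc[small]).all()

    def test_aged_subset_of_measured(self, small_survey):
        samp = small_survey.samp
        assert not (samp["aged"] & ~samp["measured"]).any()

    def test_stratified_set_scale_one_per_bin(self, reduced_spatial):
        spec = ss.SurveySpec(ages_cap=1, age_sampling="stratified",
                             age_length_group=3.0, age_space_group="set")
        sv = ss.sim_survey(reduced_spatial, spec, seed=3)
        aged = sv.samp[sv.samp["aged"]].copy()
        aged["bin"] = np.ceil(aged["length"] / 3.0 - 1e-9)
        per = aged.groupby(["sim", "set", "bin"]).size()
        assert per.max() == 1

    def test_random_ageing_cap_per_set(self, reduced_spatial):
        spec = ss.SurveySpec(ages_cap=10, age_sampling="random")
        sv = ss.sim_survey(reduced_spatial, spec, seed=4)
        samp = sv.samp
        aged = samp[samp["aged"]].groupby(["sim", "set"]).size()
        meas = samp[samp["measured"]].groupby(["sim", "set"]).size()
        expected = np.minimum(meas, 10)
        assert aged.sort_index().equals(expected[aged.index].sort_index())

    def test_sigma_zero_lengths_deterministic(self, tiny_spatial):
        spec = ss.SurveySpec(trawl_dim=(1.0, 1.0), q_table=(1.0,) * 6)
        sv = ss.sim_survey(tiny_spatial, spec, seed=6)
        growth = tiny_spatial.population.growth
        mean_len = growth.mean_length(sv.samp["age"].to_numpy())
        edges = tiny_spatial.population.length_edges
        expected = growth.bin_lengths(mean_len, edges)
        assert np.allclose(sv.samp["length"].to_numpy(), expected)

    def test_length_distribution_matches_phi(self, reduced_spatial):
        from scipy.stats import chisquare
        pop = reduced_spatial.population
        sv = ss.sim_survey(reduced_spatial, ss.SurveySpec(n_sims=3), seed=7)
        samp = sv.samp
        age = pop.ages[5]
        sub = samp[samp["age"] == age]
        assert len(sub) > 2000
        idx = np.searchsorted(pop.lengths, sub["length"].to_numpy())
        obs = np.bincount(idx, minlength=pop.lengths.size)
        exp = pop.phi[5] * len(sub)
        keep = exp > 5
        stat = chisquare(obs[keep], exp[keep] * obs[keep].sum() / exp[keep].sum())
        assert stat.pvalue > 1e-4


class TestSurveyData:
    def test_truth_is_catchability_corrected(self, small_survey, default_pop):
        q = ss.logistic_catchability(default_pop.ages)
        assert np.allclose(small_survey.I, q[:, None] * default_pop.N)
        assert np.allclose(small_survey.I_at_length,
                           default_pop.phi.T @ small_survey.I)

    def test_replicates_differ_but_reproduce(self, reduced_spatial):
        a = ss.sim_survey(reduced_spatial, ss.SurveySpec(n_sims=2), seed=11)
        b = ss.sim_survey(reduced_spatial, ss.SurveySpec(n_sims=2), seed=11)
        assert a.setdet.equals(b.setdet) and a.samp.equals(b.samp)
        s1 = a.setdet[a.setdet["sim"] == 1]["n"].to_numpy()
        s2 = a.setdet[a.setdet["sim"] == 2]["n"].to_numpy()
        assert not np.array_equal(s1, s2)

    def test_batching_invariance(self, reduced_spatial):
        whole = ss.sim_survey(reduced_spatial, ss.SurveySpec(n_sims=3), seed=12)
        part = ss.sim_survey(reduced_spatial, ss.SurveySpec(n_sims=1), seed=12,
                             first_sim=2)
        w3 = whole.setdet[whole.setdet["sim"] == 3].reset_index(drop=True)
        p3 = part.setdet.reset_index(drop=True)
        assert w3.equals(p3)

    def test_every_stratum_has_min_sets(self, small_survey, reduced_grid):
        counts = small_survey.setdet.groupby(["sim", "year", "strat"]).size()
        assert counts.min() >= 2
        n_strata = reduced_grid.cells["strat"].nunique()
        assert (small_survey.setdet.groupby(["sim", "year"])["strat"].nunique()
                == n_strata).all()

    def test_trawl_larger_than_cell_rejected(self, tiny_spatial):
        with pytest.raises(ValueError, match="trawl"):
            ss.sim_survey(tiny_spatial, ss.SurveySpec(trawl_dim=(2.0, 1.0)),
                          seed=0)


def test_set_draw_year_major_layout(reduced_grid):
    cache = _GridCache(reduced_grid, ss.SurveySpec())
    rng = np.random.default_rng(0)
    year_idx, strat_idx, cell_idx = _draw_sets(cache, 3, rng, census=False)
    assert year_idx.size == 3 * cache.n_sets_per_year
    assert np.all(np.diff(year_idx) >= 0)
    assert (cache.strat_code[cell_idx] == strat_idx).all()
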