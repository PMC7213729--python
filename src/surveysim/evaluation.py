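"""Reproduction experiments: the package's own benchmark study conditions.

These runners re-create, at desk scale, the qualitative findings the survey
simulator is built to demonstrate: design-unbiasedness of stratified totals,
the precision gain from more sets versus more sub-sampling, and the
abundance-at-age bias introduced by broad-scale age-length keys over an
age-clustered population (resolved by set-level concurrent sampling).

Problem sizes are chosen so each experiment runs in minutes on one CPU: a
20 x 20 cell grid (14 km cells over a 280 km square), and for the design
sweeps a 10-year population with mean recruitment 3e6 and a 3 km x 0.3 km
trawl so that sub-sampling caps actually bind.  docs/methods.md discusses
these choices.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from ._rng import substream
from .distribution import (DepthPrefParams, FieldParams, distribute_population,
                           matern_correlation, simulate_ays_field)
from .grid import GridParams, make_grid
from .population import (PopulationParams, sim_abundance, simulate_recruitment,
                         simulate_total_mortality)
from .stratified import StratOptions, run_strat, scale_length_frequencies, strat_error
from .survey import SurveySpec, sim_survey
from .experiment import expand_surveys, test_surveys

__all__ = ["reduced_grid_params", "conservation_check", "census_oracle",
           "unbiasedness_experiment", "set_density_experiment",
           "alk_scale_experiment", "process_recovery", "estimator_hand_checks"]


def reduced_grid_params(res: float = 14.0) -> GridParams:
    """Default survey frame geometry at a coarser (cheaper) cell size."""
    return GridParams(res=(res, res))


# ---------------------------------------------------------------------------
# conservation
# ---------------------------------------------------------------------------

def conservation_check(seed: int = 0) -> dict:
    """Max relative violation of the four bookkeeping identities on a seeded run."""
    pop = sim_abundance(seed=seed)
    grid = make_grid(reduced_grid_params())
    spatial = distribute_population(pop, grid, seed=seed)
    sv = sim_survey(spatial, SurveySpec(n_sims=1), seed=seed)

    phi_dev = np.abs(pop.phi.sum(axis=1) - 1.0).max()
    tot = pop.N.sum(axis=0)
    nal_dev = np.abs(pop.N_at_length.sum(axis=0) - tot).max() / tot.max()
    cell_dev = (np.abs(spatial.abundance.sum(axis=2) - pop.N).max() /
                max(pop.N.max(), 1.0))
    freq = scale_length_frequencies(sv.samp, sv.setdet, pop.params.length_group)
    per_set = freq.groupby(["sim", "year", "set"])["n_l"].sum().reset_index()
    per_set = per_set.merge(sv.setdet[["sim", "year", "set", "n"]],
                            on=["sim", "year", "set"])
    freq_dev = (np.abs(per_set["n_l"] - per_set["n"]).max() /
                max(per_set["n"].max(), 1.0))
    return {"phi_rowsum_dev": float(phi_dev),
            "n_at_length_dev": float(nal_dev),
            "cell_sum_dev": float(cell_dev),
            "set_freq_dev": float(freq_dev)}


# ---------------------------------------------------------------------------
# census oracle
# ---------------------------------------------------------------------------

def census_oracle(seed: int = 0) -> dict:
    """Exhaustive, perfectly catchable survey of an integer-valued population.

    Survival exp(-Z) = 1/2 exactly and recruitment a power of two times the
    cell count, so every cell abundance is an exact float integer; one set
    per cell with A_trawl = A_cell and q = 1 then recovers the population
    exactly and all stratified errors must be zero.
    """
    A, Y = 6, 3
    pop = sim_abundance(PopulationParams(
        ages=tuple(range(1, A + 1)), years=tuple(range(1, Y + 1)),
        mu_r=225 * 2 ** A, sigma_r=0.0, mu_Z=float(np.log(2)), sigma_delta=0.0,
        sigma_L=0.0), seed=seed)
    grid = make_grid(GridParams(x_range=(0, 15), y_range=(0, 15), res=(1, 1),
                                depth_range=(0, 100), shelf_width=0.0,
                                strat_breaks=(0.0, 100.0), strat_splits=0))
    spatial = distribute_population(
        pop, grid, FieldParams(sd=0.0, group_ages=None),
        DepthPrefParams(mu_d=50.0, sigma_d=1e9), seed=seed)
    spec = SurveySpec(census=True, trawl_dim=(1.0, 1.0),
                      q_table=tuple([1.0] * A), lengths_cap=10 ** 9,
                      ages_cap=10 ** 9, age_space_group="set",
                      age_length_group=pop.params.length_group)
    sv = sim_survey(spatial, spec, seed=seed)
    est = run_strat(sv, StratOptions(alk_scale="set"))
    err = strat_error(est, sv)
    scale = pop.N.sum()
    return {
        "total_max_abs_err": float(err.total_strat_error["error"].abs().max()),
        "length_max_abs_err": float(err.length_strat_error["error"].abs().max()),
        "age_max_abs_err": float(err.age_strat_error["error"].abs().max()),
        "total_rmse": float(err.total_strat_error_stats["RMSE"].iloc[0]),
        "var_max": float(est.total_strat["var"].abs().max()),
        "scale": float(scale),
    }


# ---------------------------------------------------------------------------
# design-unbiasedness of stratified totals
# ---------------------------------------------------------------------------

def unbiasedness_experiment(seed: int = 0, n_reps: int = 500,
                            batch: int = 25) -> pd.DataFrame:
    """Per-year mean relative error of the stratified total over replicates.

    Default population over the reduced grid, default survey protocol.
    Returns per-year mean relative error with its Monte-Carlo standard error.
    """
    pop = sim_abundance(seed=seed)
    grid = make_grid(reduced_grid_params())
    spatial = distribute_population(pop, grid, seed=seed)
    rel = []
    done = 0
    while done < n_reps:
        k = min(batch, n_reps - done)
        sv = sim_survey(spatial, SurveySpec(n_sims=k), seed=seed, first_sim=done)
        est = run_strat(sv)
        err = strat_error(est, sv)
        tab = err.total_strat_error
        rel.append(pd.DataFrame({"sim": tab["sim"], "year": tab["year"],
                                 "rel_err": tab["error"] / tab["I"]}))
        done += k
    rel = pd.concat(rel, ignore_index=True)
    out = rel.groupby("year")["rel_err"].agg(["mean", "std", "count"]).reset_index()
    out["se"] = out["std"] / np.sqrt(out["count"])
    out["z"] = out["mean"] / out["se"]
    return out


# ---------------------------------------------------------------------------
# set density vs sub-sampling effort
# ---------------------------------------------------------------------------

def _sweep_population(seed: int):
    pop = sim_abundance(PopulationParams(years=tuple(range(1, 11)), mu_r=3e6),
                        seed=seed)
    grid = make_grid(reduced_grid_params())
    return distribute_population(pop, grid, seed=seed)


_SWEEP_TRAWL = (3.0, 0.3)  # larger trawl so per-set catches make caps bind


def set_density_experiment(seed: int = 0, n_reps: int = 200) -> pd.DataFrame:
    """RMSE of stratified estimates across a set-density x lengths-cap grid.

    Designs: set_den in {0.5, 1, 2, 5}/1000 crossed with lengths_cap in
    {25, 100}; n_reps replicate surveys each over one fixed population.
    """
    spatial = _sweep_population(seed)
    designs = expand_surveys(set_den=(0.5e-3, 1e-3, 2e-3, 5e-3),
                             lengths_cap=(25, 100), ages_cap=(10,))
    base = SurveySpec(trawl_dim=_SWEEP_TRAWL)
    res = test_surveys(spatial, designs, base_spec=base,
                       n_sims=min(25, n_reps), n_loops=max(1, n_reps // 25),
                       seed=seed)
    out = designs.merge(res.total_strat_error_stats, on="survey") \
        .merge(res.length_strat_error_stats, on="survey",
               suffixes=("_total", "_length"))
    return out


# ---------------------------------------------------------------------------
# age-length-key scale and at-age bias
# ---------------------------------------------------------------------------

def _clustered_population(seed: int):
    """Age-clustered spatial population: tight Matern range, independent ages."""
    pop = sim_abundance(PopulationParams(years=tuple(range(1, 11)), mu_r=3e6),
                        seed=seed)
    grid = make_grid(reduced_grid_params())
    field = FieldParams(sd=2.8, corr_range=40.0, lambda_=1.0,
                        phi_age=0.5, phi_year=0.9, group_ages=None)
    return distribute_population(pop, grid, field, seed=seed)


def alk_scale_experiment(seed: int = 0, n_reps: int = 300,
                         batch: int = 25) -> dict:
    """At-age bias: division-pooled ageing + division ALK vs set-level
    concurrent ageing + set ALK, over an age-clustered population.

    Returns per-age mean error (relative to mean true abundance at age) and
    its Monte-Carlo SE for both protocols.
    """
    spatial = _clustered_population(seed)
    protocols = {
        "division": (1, SurveySpec(trawl_dim=_SWEEP_TRAWL, lengths_cap=100,
                                   ages_cap=10, age_sampling="stratified",
                                   age_length_group=1.0,
                                   age_space_group="division"),
                     StratOptions(alk_scale="division")),
        "set": (2, SurveySpec(trawl_dim=_SWEEP_TRAWL, lengths_cap=100,
                              ages_cap=1, age_sampling="stratified",
                              age_length_group=3.0, age_space_group="set"),
                StratOptions(alk_scale="set")),
    }
    out = {}
    for name, (stream, spec, opts) in protocols.items():
        frames = []
        done = 0
        while done < n_reps:
            k = min(batch, n_reps - done)
            sv = sim_survey(spatial, replace(spec, n_sims=k), seed=seed,
                            first_sim=done, stream=stream)
            est = run_strat(sv, opts)
            err = strat_error(est, sv)
            frames.append(err.age_strat_error)
            done += k
        tab = pd.concat(frames, ignore_index=True)
        per_age = tab.groupby("age").agg(
            me=("error", "mean"), sd=("error", "std"), n=("error", "size"),
            I_mean=("I", "mean")).reset_index()
        per_age["se"] = per_age["sd"] / np.sqrt(per_age["n"])
        per_age["z"] = per_age["me"] / per_age["se"]
        per_age["rel_me"] = per_age["me"] / per_age["I_mean"]
        out[name] = per_age
    out["abs_me_division"] = float(out["division"]["me"].abs().sum())
    out["abs_me_set"] = float(out["set"]["me"].abs().sum())
    out["max_abs_z_division"] = float(out["division"]["z"].abs().max())
    out["max_abs_z_set"] = float(out["set"]["z"].abs().max())
    return out


# ---------------------------------------------------------------------------
# recovery of the statistical processes behind the simulator
# ---------------------------------------------------------------------------

def process_recovery(seed: int = 0, n_mort: int = 10_000, n_rec: int = 2_000,
                     n_field: int = 10_000, n_corr: int = 1_000) -> dict:
    """Monte-Carlo recovery of the generator parameters.

    Estimates the mortality AR1 correlations and variance, the recruitment
    random-walk increment variance, the field marginal SD and the spatial
    correlogram against the Matern curve.
    """
    ages = np.arange(1, 21)
    years = np.arange(1, 21)
    mu_Z, sd_d, pa, py = 0.5, 0.2, 0.9, 0.5

    # mortality process: pooled lag-1 products (the process is zero-mean with
    # known variance, so moment estimators need no centring)
    s_aa = s_yy = s_00 = 0.0
    n_aa = n_yy = n_00 = 0
    for i in range(n_mort):
        Z = simulate_total_mortality(ages, years, mu_Z, sd_d, pa, py,
                                     seed=substream(seed, "mort", i))
        d = np.log(Z) - np.log(mu_Z)
        s_aa += (d[:-1, :] * d[1:, :]).sum(); n_aa += d[:-1, :].size
        s_yy += (d[:, :-1] * d[:, 1:]).sum(); n_yy += d[:, :-1].size
        s_00 += (d * d).sum(); n_00 += d.size
    var_hat = s_00 / n_00
    phi_age_hat = (s_aa / n_aa) / var_hat
    phi_year_hat = (s_yy / n_yy) / var_hat

    # recruitment random walk: variance of log increments
    incs = []
    for i in range(n_rec):
        R = simulate_recruitment(years, 3e7, 0.5, seed=substream(seed, "rec", i))
        incs.append(np.diff(np.log(R)))
    inc_var = float(np.var(np.concatenate(incs), ddof=1))

    # field marginal variance on a small grid
    gsmall = make_grid(GridParams(x_range=(0, 50), y_range=(0, 50), res=(10, 10),
                                  depth_range=(0, 100), shelf_width=0.0,
                                  strat_breaks=(0.0, 100.0), strat_splits=0))
    fp = FieldParams(sd=2.8, corr_range=30.0, group_ages=None)
    tot = 0.0
    cnt = 0
    for i in range(n_field):
        xi = simulate_ays_field(gsmall, [1], [1], fp,
                                seed=substream(seed, "field", i))
        tot += (xi ** 2).sum(); cnt += xi.size
    field_sd_hat = float(np.sqrt(tot / cnt))

    # spatial correlogram on a 15x15 grid vs the Matern curve
    gcorr = make_grid(GridParams(x_range=(0, 150), y_range=(0, 150), res=(10, 10),
                                 depth_range=(0, 100), shelf_width=0.0,
                                 strat_breaks=(0.0, 100.0), strat_splits=0))
    fpc = FieldParams(sd=1.0, corr_range=60.0, group_ages=None)
    xy = gcorr.cells[["x", "y"]].to_numpy()
    dist = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
    fields = np.empty((n_corr, gcorr.n_cells))
    for i in range(n_corr):
        fields[i] = simulate_ays_field(gcorr, [1], [1], fpc,
                                       seed=substream(seed, "corr", i))[0, 0]
    emp_cov = fields.T @ fields / n_corr
    emp_var = np.diag(emp_cov)
    emp_corr = emp_cov / np.sqrt(emp_var[:, None] * emp_var[None, :])
    lags = np.array([10.0, 20.0, 30.0, 60.0, 90.0])
    corr_dev = 0.0
    correlogram = {}
    for lag in lags:
        mask = np.abs(dist - lag) < 1e-6
        emp = float(emp_corr[mask].mean())
        theo = float(matern_correlation(lag, fpc.corr_range, fpc.lambda_))
        correlogram[lag] = (emp, theo)
        corr_dev = max(corr_dev, abs(emp - theo))

    return {"phi_age_hat": float(phi_age_hat),
            "phi_year_hat": float(phi_year_hat),
            "sigma_delta_var_hat": float(var_hat),
            "recruit_increment_var_hat": inc_var,
            "field_sd_hat": field_sd_hat,
            "correlogram": correlogram,
            "correlogram_max_dev": float(corr_dev)}


# ---------------------------------------------------------------------------
# estimator hand checks
# ---------------------------------------------------------------------------

def estimator_hand_checks() -> dict:
    """Tiny closed-form checks of the estimator arithmetic."""
    from .stratified import (_error_metrics, build_alk, stratified_estimate)

    # one stratum of 100 trawlable units, sets catching 2 and 4 fish
    per_set = pd.DataFrame({"sim": 1, "year": 1, "strat": 1,
                            "set": [1, 2], "value": [2.0, 4.0]})
    areas = pd.DataFrame({"division": [1], "strat": [1], "n_cells": [100],
                          "area": [100.0]})
    est = stratified_estimate(per_set, areas, trawl_dim=(1.0, 1.0))

    # length scaling: 10 measured in a bin, 50 measured of 100 caught
    scale_example = 10 * 100 / 50

    # ALK from one bin holding aged fish of ages {3, 3, 4}
    setdet = pd.DataFrame({"sim": [1], "year": [1], "set": [1],
                           "division": [1], "strat": [1], "n": [3]})
    samp = pd.DataFrame({"sim": 1, "year": 1, "set": 1, "fish": [1, 2, 3],
                         "age": [3, 3, 4], "length": [25.0, 26.0, 27.0],
                         "measured": True, "aged": True})
    alk = build_alk(samp, setdet, alk_scale="division", length_group=3.0)
    p3 = float(alk.loc[alk["age"] == 3, "p"].iloc[0])
    p4 = float(alk.loc[alk["age"] == 4, "p"].iloc[0])

    stats = _error_metrics(np.array([1.0, -1.0]))
    return {"I_hat_2_4": float(est["I_hat"].iloc[0]),
            "length_scaling_10_100_50": scale_example,
            "alk_334_p3": p3, "alk_334_p4": p4,
            "pm1_ME": stats["ME"], "pm1_MAE": stats["MAE"],
            "pm1_MSE": stats["MSE"], "pm1_RMSE": stats["RMSE"]}
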