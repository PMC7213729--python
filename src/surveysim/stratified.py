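"""Design-based stratified analysis of simulated survey data.

Estimation follows the classic stratified-random estimators with a finite
population correction, the population size of a stratum being its count of
trawlable units N_h = A_strat / A_trawl:

    I_hat = sum_h N_h * ybar_h
    Var   = sum_h N_h^2 * (1 - n_h / N_h) * s_h^2 / n_h

applied to per-set totals, per-set length frequencies (measured counts scaled
by the set's measured-to-caught ratio n_i / m_i) and per-set age frequencies
(length frequencies pushed through an age-length key, ALK).  The ALK is the
observed proportion of aged fish at each age within a length bin, built and
applied per division, stratum or set (always within year and replicate).

Length bins with scaled frequency but no aged fish at the chosen scale borrow
the key of the nearest populated bin (ties to the shorter bin); occurrences
are counted and logged.  Zero-catch sets enter stratum means as zeros, which
design-unbiasedness requires.

Error statistics (ME, MAE, MSE, RMSE) compare estimates against the true
abundance available to the survey, I = q_a * N[a, y], pooling years,
replicates and (for at-length / at-age) bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .survey import SurveyData

__all__ = ["StratOptions", "StratEstimates", "ErrorStats",
           "scale_length_frequencies", "build_alk", "apply_alk",
           "stratified_estimate", "run_strat", "strat_error"]

logger = logging.getLogger(__name__)

_SCALES = ("division", "strat", "set")


@dataclass(frozen=True)
class StratOptions:
    """Analysis options: length-bin width (or "inherit" from the growth model)
    and the scale at which age-length keys are built and applied."""

    length_group: object = "inherit"
    alk_scale: str = "division"

    def __post_init__(self):
        if self.alk_scale not in _SCALES:
            raise ValueError(f'alk_scale must be one of {_SCALES}')
        if self.length_group != "inherit" and not float(self.length_group) > 0:
            raise ValueError('length_group must be positive or "inherit"')


@dataclass(frozen=True)
class StratEstimates:
    """Stratified estimates per replicate and year (total / at-length / at-age)."""

    total_strat: pd.DataFrame = field(repr=False)
    length_strat: pd.DataFrame = field(repr=False)
    age_strat: pd.DataFrame = field(repr=False)
    options: StratOptions = StratOptions()
    length_group: float = 3.0


@dataclass(frozen=True)
class ErrorStats:
    """Paired (I_hat, I) tables and pooled error metrics per estimate type."""

    total_strat_error: pd.DataFrame = field(repr=False)
    length_strat_error: pd.DataFrame = field(repr=False)
    age_strat_error: pd.DataFrame = field(repr=False)
    total_strat_error_stats: pd.DataFrame = field(repr=False)
    length_strat_error_stats: pd.DataFrame = field(repr=False)
    age_strat_error_stats: pd.DataFrame = field(repr=False)

    def summary(self) -> pd.DataFrame:
        rows = []
        for kind in ("total", "length", "age"):
            st = getattr(self, f"{kind}_strat_error_stats").copy()
            st.insert(0, "estimate", kind)
            rows.append(st)
        return pd.concat(rows, ignore_index=True)


def _error_metrics(err: np.ndarray) -> dict:
    err = np.asarray(err, dtype=float)
    me = float(err.mean())
    mae = float(np.abs(err).mean())
    mse = float((err ** 2).mean())
    return {"ME": me, "MAE": mae, "MSE": mse, "RMSE": float(np.sqrt(mse))}


# ---------------------------------------------------------------------------
# public, table-level operations (contract surface; used for small data and
# as an independent route to cross-check the vectorized run_strat engine)
# ---------------------------------------------------------------------------

def _bin_col(length: pd.Series, width: float) -> pd.Series:
    """Analysis length-bin label (upper edge) of a recorded length."""
    return width * np.ceil(length / width - 1e-9)


def scale_length_frequencies(samp: pd.DataFrame, setdet: pd.DataFrame,
                             length_group: float) -> pd.DataFrame:
    """Per-set length frequencies n_{l,i} = m_{l,i} * n_i / m_i.

    Zero-catch sets are retained with zero frequency (as a row with length
    NaN) so they still enter stratum means.
    """
    meas = samp[samp["measured"]].copy()
    meas["length_bin"] = _bin_col(meas["length"], float(length_group))
    m_li = (meas.groupby(["sim", "year", "set", "length_bin"])
            .size().rename("m_l").reset_index())
    m_i = meas.groupby(["sim", "year", "set"]).size().rename("m")
    base = setdet[["sim", "year", "set", "n"]].copy()
    base = base.merge(m_i.reset_index(), on=["sim", "year", "set"], how="left")
    base["m"] = base["m"].fillna(0).astype(int)
    bad = (base["n"] > 0) & (base["m"] == 0)
    if bad.any():
        raise ValueError("sets with catch but no measured fish: "
                         f"{base.loc[bad, 'set'].tolist()[:10]}")
    out = m_li.merge(base, on=["sim", "year", "set"], how="outer")
    out["m_l"] = out["m_l"].fillna(0)
    with np.errstate(invalid="ignore"):
        out["n_l"] = np.where(out["m"] > 0, out["m_l"] * out["n"] / out["m"], 0.0)
    return out[["sim", "year", "set", "length_bin", "m_l", "n_l"]]


def _unit_col(df: pd.DataFrame, setdet: pd.DataFrame, alk_scale: str) -> pd.Series:
    if alk_scale == "set":
        return df["set"]
    key = setdet.set_index(["sim", "year", "set"])[alk_scale]
    return df.set_index(["sim", "year", "set"]).index.map(key)


def build_alk(samp: pd.DataFrame, setdet: pd.DataFrame, alk_scale: str = "division",
              length_group: float = 3.0) -> pd.DataFrame:
    """Age-length key: p(age | length bin, unit) from aged fish, per sim and year."""
    if alk_scale not in _SCALES:
        raise ValueError(f"alk_scale must be one of {_SCALES}")
    aged = samp[samp["aged"]].copy()
    if aged.empty:
        raise ValueError("no aged fish to build an age-length key from")
    aged["length_bin"] = _bin_col(aged["length"], float(length_group))
    aged["unit"] = _unit_col(aged, setdet, alk_scale).to_numpy()
    counts = (aged.groupby(["sim", "year", "unit", "length_bin", "age"])
              .size().rename("m_al").reset_index())
    totals = counts.groupby(["sim", "year", "unit", "length_bin"])["m_al"].transform("sum")
    counts["p"] = counts["m_al"] / totals
    return counts


def apply_alk(freq: pd.DataFrame, alk: pd.DataFrame, setdet: pd.DataFrame,
              alk_scale: str = "division") -> pd.DataFrame:
    """Convert per-set length frequencies to age frequencies n_{a,i}.

    Bins without aged fish at their unit borrow the nearest populated bin's
    key (ties to the shorter bin); a unit with frequency but no aged fish at
    all is a sampling-contract violation and raises.
    """
    f = freq[freq["n_l"] > 0].copy()
    if f.empty:
        cols = ["sim", "year", "set", "age", "n_a"]
        return pd.DataFrame({c: [] for c in cols})
    f["unit"] = _unit_col(f, setdet, alk_scale).to_numpy()
    out = []
    alk_g = dict(tuple(alk.groupby(["sim", "year", "unit"])))
    for (sim, year, unit), grp in f.groupby(["sim", "year", "unit"]):
        key = alk_g.get((sim, year, unit))
        if key is None or key.empty:
            raise ValueError(f"no aged fish at alk_scale={alk_scale!r} for "
                             f"sim={sim}, year={year}, unit={unit}")
        populated = np.sort(key["length_bin"].unique())
        for _, row in grp.iterrows():
            lb = row["length_bin"]
            if lb in populated:
                use = lb
            else:
                d = np.abs(populated - lb)
                use = populated[np.lexsort((populated, d))][0]  # tie -> lower bin
                logger.debug("ALK bin %s empty for unit %s; borrowing bin %s",
                             lb, unit, use)
            k = key[key["length_bin"] == use]
            out.append(pd.DataFrame({
                "sim": sim, "year": year, "set": row["set"],
                "age": k["age"].to_numpy(),
                "n_a": row["n_l"] * k["p"].to_numpy(),
            }))
    res = pd.concat(out, ignore_index=True)
    return res.groupby(["sim", "year", "set", "age"], as_index=False)["n_a"].sum()


def stratified_estimate(per_set_values: pd.DataFrame, strat_areas: pd.DataFrame,
                        trawl_dim) -> pd.DataFrame:
    """Stratified mean-expansion estimate and variance per (sim, year).

    ``per_set_values`` needs columns sim, year, strat, set, value; every
    surveyed set must appear (zero catches as zeros).
    """
    A_trawl = float(trawl_dim[0]) * float(trawl_dim[1])
    areas = strat_areas.set_index("strat")["area"]
    out = []
    for (sim, year), grp in per_set_values.groupby(["sim", "year"]):
        agg = grp.groupby("strat")["value"].agg(["mean", "var", "count"])
        if (agg["count"] < 2).any():
            bad = agg.index[agg["count"] < 2].tolist()
            raise ValueError(f"strata {bad} have fewer than 2 sets in year {year}; "
                             "variance is undefined")
        N_h = areas.loc[agg.index].to_numpy() / A_trawl
        n_h = agg["count"].to_numpy()
        mean_h = agg["mean"].to_numpy()
        var_h = agg["var"].to_numpy()
        I_hat = float((N_h * mean_h).sum())
        var = float((N_h ** 2 * (1 - n_h / N_h) * var_h / n_h).sum())
        out.append({"sim": sim, "year": year, "I_hat": I_hat, "var": var})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# vectorized engine behind run_strat
# ---------------------------------------------------------------------------

def _nearest_populated(populated: np.ndarray) -> np.ndarray:
    """(K, L) bool -> (K, L) int: nearest populated bin per row (ties to the
    lower bin); -1 where a row has no populated bin."""
    K, L = populated.shape
    idx = np.arange(L)
    left = np.where(populated, idx, -1)
    left = np.maximum.accumulate(left, axis=1)
    right = np.where(populated, idx, 2 * L)
    right = np.minimum.accumulate(right[:, ::-1], axis=1)[:, ::-1]
    dl = np.where(left >= 0, idx - left, np.inf)
    dr = np.where(right < 2 * L, right - idx, np.inf)
    use_left = dl <= dr  # tie -> lower bin
    out = np.where(use_left, left, np.where(np.isinf(dr), -1, right))
    return out.astype(np.int64)


def _strat_moments(g: np.ndarray, values: np.ndarray, n_groups: int):
    """Per-group count, mean and sample variance of per-set values.

    ``values`` may be (n_sets,) or (n_sets, m); moments are per column.
    """
    v = values if values.ndim == 2 else values[:, None]
    cnt = np.bincount(g, minlength=n_groups).astype(float)
    sums = np.zeros((n_groups, v.shape[1]))
    sq = np.zeros((n_groups, v.shape[1]))
    np.add.at(sums, g, v)
    np.add.at(sq, g, v * v)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / cnt[:, None]
        var = (sq - cnt[:, None] * mean ** 2) / (cnt[:, None] - 1)
    var = np.clip(var, 0.0, None)  # guard tiny negative rounding
    return cnt, np.nan_to_num(mean), np.nan_to_num(var)


def run_strat(survey: SurveyData, options: StratOptions | None = None) -> StratEstimates:
    """Full stratified analysis: length scaling, ALK, expansion to totals."""
    opts = options if options is not None else StratOptions()
    pop = survey.spatial.population
    grid = survey.spatial.grid
    ages = pop.ages
    years = pop.years
    A, Y = ages.size, years.size

    sim_group = float(pop.params.length_group)
    w = sim_group if opts.length_group == "inherit" else float(opts.length_group)

    areas = grid.strat_areas()
    strat_ids = areas["strat"].to_numpy()
    H = strat_ids.size
    strat_pos = {s: i for i, s in enumerate(strat_ids)}
    div_ids = np.unique(areas["division"].to_numpy())
    div_pos = {d: i for i, d in enumerate(div_ids)}
    div_code_of_strat = np.array([div_pos[d] for d in areas["division"]])
    A_trawl = survey.spec.trawl_area
    N_h = areas["area"].to_numpy() / A_trawl

    sd = survey.setdet
    sp = survey.samp
    sd_sim = sd["sim"].to_numpy()
    sp_sim = sp["sim"].to_numpy()
    sims = np.unique(sd_sim)

    tot_rows, len_rows, age_rows = [], [], []
    n_borrowed = 0

    for sim in sims:
        s_mask = sd_sim == sim
        f_mask = sp_sim == sim
        n_i = sd["n"].to_numpy()[s_mask].astype(float)
        set_ids = sd["set"].to_numpy()[s_mask]
        n_sets = set_ids.size
        if not np.array_equal(set_ids, np.arange(1, n_sets + 1)):
            raise ValueError("setdet must number sets 1..n within each replicate")
        year_pos = np.searchsorted(years, sd["year"].to_numpy()[s_mask])
        strat_code = np.array([strat_pos[s] for s in sd["strat"].to_numpy()[s_mask]])

        f_set = sp["set"].to_numpy()[f_mask].astype(np.int64) - 1
        f_len = sp["length"].to_numpy()[f_mask].astype(float)
        f_age = np.searchsorted(ages, sp["age"].to_numpy()[f_mask])
        f_meas = sp["measured"].to_numpy()[f_mask]
        f_aged = sp["aged"].to_numpy()[f_mask]

        bin_full = np.ceil(f_len / w - 1e-9).astype(np.int64) - 1
        mi = np.flatnonzero(f_meas)
        occ = np.unique(bin_full[mi]) if mi.size else np.array([0], dtype=np.int64)
        L = occ.size
        occ_of = np.full(int(bin_full.max(initial=0)) + 2, -1, dtype=np.int64)
        occ_of[occ] = np.arange(L)

        m_li = np.zeros((n_sets, L))
        np.add.at(m_li, (f_set[mi], occ_of[bin_full[mi]]), 1.0)
        m_i = m_li.sum(axis=1)
        if np.any((n_i > 0) & (m_i == 0)):
            bad = set_ids[(n_i > 0) & (m_i == 0)][:10]
            raise ValueError(f"sets with catch but no measured fish: {bad.tolist()}")
        with np.errstate(invalid="ignore"):
            scale = np.where(m_i > 0, n_i / np.where(m_i > 0, m_i, 1.0), 0.0)
        n_li = m_li * scale[:, None]

        # --- age-length key ---------------------------------------------
        if opts.alk_scale == "set":
            key_of_set = np.arange(n_sets)
            n_keys = n_sets
        else:
            unit = (div_code_of_strat[strat_code] if opts.alk_scale == "division"
                    else strat_code)
            n_unit = div_ids.size if opts.alk_scale == "division" else H
            key_of_set = year_pos * n_unit + unit
            n_keys = Y * n_unit
        counts = np.zeros((n_keys, L, A))
        ai = np.flatnonzero(f_aged)
        if ai.size:
            np.add.at(counts, (key_of_set[f_set[ai]], occ_of[bin_full[ai]], f_age[ai]), 1.0)
        rowsum = counts.sum(axis=2)
        populated = rowsum > 0
        freq_per_key = np.zeros((n_keys, L))
        np.add.at(freq_per_key, key_of_set, n_li)
        need = freq_per_key > 0
        no_key = need.any(axis=1) & ~populated.any(axis=1)
        if no_key.any():
            raise ValueError(
                f"no aged fish at alk_scale={opts.alk_scale!r} for key(s) "
                f"{np.flatnonzero(no_key)[:10].tolist()} in replicate {sim}")
        nearest = _nearest_populated(populated)
        borrow = need & ~populated
        n_borrowed += int(borrow.sum())
        use = np.where(nearest >= 0, nearest, 0)
        with np.errstate(invalid="ignore"):
            P = counts / np.where(rowsum > 0, rowsum, 1.0)[:, :, None]
        P_eff = np.take_along_axis(P, use[:, :, None], axis=1)
        n_ai = np.einsum("sl,sla->sa", n_li, P_eff[key_of_set])

        # --- stratified expansion ---------------------------------------
        g = year_pos * H + strat_code
        nG = Y * H
        cnt, mean_t, var_t = _strat_moments(g, n_i, nG)
        _, mean_l, var_l = _strat_moments(g, n_li, nG)
        _, mean_a, var_a = _strat_moments(g, n_ai, nG)
        cnt2 = cnt.reshape(Y, H)
        sampled = cnt2 > 0
        single = cnt2 == 1
        if single.any():
            yy, hh = np.nonzero(single)
            raise ValueError(f"stratum {strat_ids[hh[0]]} has a single set in year "
                             f"{years[yy[0]]}; variance is undefined")
        fpc = np.where(sampled, 1.0 - cnt2 / N_h[None, :], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            wvar = np.where(sampled, N_h[None, :] ** 2 * fpc / cnt2, 0.0)

        def expand(mean, var, m):
            mean = mean.reshape(Y, H, m)
            var = var.reshape(Y, H, m)
            I_hat = (N_h[None, :, None] * mean * sampled[:, :, None]).sum(axis=1)
            V = (wvar[:, :, None] * var).sum(axis=1)
            return I_hat, V

        It, Vt = expand(mean_t, var_t, 1)
        Il, Vl = expand(mean_l, var_l, L)
        Ia, Va = expand(mean_a, var_a, A)

        tot_rows.append(pd.DataFrame({
            "sim": sim, "year": years, "I_hat": It[:, 0], "var": Vt[:, 0]}))
        len_rows.append(pd.DataFrame({
            "sim": sim,
            "year": np.repeat(years, L),
            "length": np.tile((occ + 1) * w, Y),
            "I_hat": Il.ravel(),
            "var": Vl.ravel()}))
        age_rows.append(pd.DataFrame({
            "sim": sim,
            "year": np.repeat(years, A),
            "age": np.tile(ages, Y),
            "I_hat": Ia.ravel(),
            "var": Va.ravel()}))

    if n_borrowed:
        logger.info("ALK: %d empty length-bin/unit combinations borrowed the "
                    "nearest populated bin's key", n_borrowed)
    return StratEstimates(total_strat=pd.concat(tot_rows, ignore_index=True),
                          length_strat=pd.concat(len_rows, ignore_index=True),
                          age_strat=pd.concat(age_rows, ignore_index=True),
                          options=opts, length_group=w)


def _rebin_truth_lengths(I_at_length: np.ndarray, sim_labels: np.ndarray,
                         w: float) -> tuple[np.ndarray, np.ndarray]:
    """Aggregate the true at-length index from simulation bins to analysis bins."""
    target = w * np.ceil(sim_labels / w - 1e-9)
    labels = np.unique(target)
    out = np.zeros((labels.size, I_at_length.shape[1]))
    idx = np.searchsorted(labels, target)
    np.add.at(out, idx, I_at_length)
    return labels, out


def strat_error(estimates: StratEstimates, survey: SurveyData) -> ErrorStats:
    """Pair stratified estimates with catchability-corrected truth and score them."""
    pop = survey.spatial.population
    years = pop.years
    ages = pop.ages
    I_tot = survey.I.sum(axis=0)

    tot = estimates.total_strat.copy()
    truth_y = pd.Series(I_tot, index=years)
    tot["I"] = tot["year"].map(truth_y)
    if tot["I"].isna().any():
        raise ValueError("estimate years do not align with truth years")
    tot["error"] = tot["I_hat"] - tot["I"]
    tot_stats = pd.DataFrame([_error_metrics(tot["error"])])

    # at length: union of bins with nonzero truth or estimate, zero-filled
    sim_w = float(pop.params.length_group)
    if abs(estimates.length_group / sim_w - round(estimates.length_group / sim_w)) > 1e-9:
        raise ValueError("analysis length_group must be a multiple of the "
                         "simulation length bin width")
    labels, truth_l = _rebin_truth_lengths(survey.I_at_length, pop.lengths,
                                           estimates.length_group)
    truth_df = pd.DataFrame(truth_l, index=labels, columns=years) \
        .rename_axis("length").reset_index() \
        .melt(id_vars="length", var_name="year", value_name="I")
    truth_df = truth_df[truth_df["I"] > 0]
    est_l = estimates.length_strat
    sims = np.unique(estimates.total_strat["sim"])
    base = truth_df.merge(pd.DataFrame({"sim": sims}), how="cross")
    le = base.merge(est_l, on=["sim", "year", "length"], how="outer")
    # bins absent from truth_df have zero truth; unobserved bins estimate zero
    le["I"] = le["I"].fillna(0.0)
    le["I_hat"] = le["I_hat"].fillna(0.0)
    le = le[(le["I"] > 0) | (le["I_hat"] != 0)]
    le["error"] = le["I_hat"] - le["I"]
    len_stats = pd.DataFrame([_error_metrics(le["error"])])

    # at age: full age x year grid
    truth_a = pd.DataFrame(survey.I, index=ages, columns=years) \
        .rename_axis("age").reset_index() \
        .melt(id_vars="age", var_name="year", value_name="I")
    ae = truth_a.merge(pd.DataFrame({"sim": sims}), how="cross") \
        .merge(estimates.age_strat, on=["sim", "year", "age"], how="left")
    ae["I_hat"] = ae["I_hat"].fillna(0.0)
    ae["error"] = ae["I_hat"] - ae["I"]
    age_stats = pd.DataFrame([_error_metrics(ae["error"])])

    cols_t = ["sim", "year", "I_hat", "I", "error"]
    cols_l = ["sim", "year", "length", "I_hat", "I", "error"]
    cols_a = ["sim", "year", "age", "I_hat", "I", "error"]
    return ErrorStats(
        total_strat_error=tot[cols_t],
        length_strat_error=le[cols_l].sort_values(["sim", "year", "length"])
            .reset_index(drop=True),
        age_strat_error=ae[cols_a].sort_values(["sim", "year", "age"])
            .reset_index(drop=True),
        total_strat_error_stats=tot_stats,
        length_strat_error_stats=len_stats,
        age_strat_error_stats=age_stats,
    )
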