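"""Stratified-random trawl survey simulation.

One survey replicate proceeds, for each year, as:

1. set allocation — every stratum receives max(min_sets,
   round(A_strat * set_den)) sets at cells drawn uniformly *with* replacement
   from the stratum's cells (several sets may land in one cell);
2. catch — each set catches Binomial(N[a, y, cell], (A_trawl / A_cell) * q_a)
   fish per age; when sets share a cell the cell's fish are first partitioned
   across them by an equal-probability multinomial, so the summed catch never
   exceeds the cell abundance.  The survey never depletes the population
   between years;
3. lengths — every caught fish gets a binned length from the population's
   lognormal length-at-age law;
4. sub-sampling — per set at most ``lengths_cap`` fish are measured; of the
   measured fish, at most ``ages_cap`` are aged per length group
   (``age_length_group`` cm) per spatial group (division, stratum or set) in
   length-stratified mode, or at most ``ages_cap`` per set in random mode.

Catchability at age is logistic in age (steepness k, midpoint x0) unless an
explicit per-age table is supplied.  A ``census`` survey places exactly one
set in every cell (useful as an exact oracle when A_trawl == A_cell and
q == 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from ._rng import as_rng
from .distribution import SpatialPopulation
from .grid import SurveyGrid

__all__ = ["SurveySpec", "SurveyData", "logistic_catchability", "allocate_sets",
           "sim_survey"]


def logistic_catchability(age, k: float = 2.0, x0: float = 3.0):
    """q(age) = 1 / (1 + exp(-k * (age - x0)))."""
    return 1.0 / (1.0 + np.exp(-k * (np.asarray(age, dtype=float) - x0)))


@dataclass(frozen=True)
class SurveySpec:
    """Survey protocol settings (defaults mirror a typical groundfish survey)."""

    n_sims: int = 1
    q_k: float = 2.0
    q_x0: float = 3.0
    q_table: Optional[tuple] = None  # per-age catchability overriding the logistic
    trawl_dim: tuple = (1.5, 0.02)
    min_sets: int = 2
    set_den: float = 2.0 / 1000.0
    lengths_cap: int = 500
    ages_cap: int = 10
    age_sampling: str = "stratified"
    age_length_group: float = 1.0
    age_space_group: str = "division"
    census: bool = False

    def __post_init__(self):
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if self.set_den <= 0:
            raise ValueError("set_den must be > 0")
        if self.min_sets < 1:
            raise ValueError("min_sets must be >= 1")
        if self.lengths_cap < 1 or self.ages_cap < 1:
            raise ValueError("sampling caps must be >= 1")
        if self.age_sampling not in ("stratified", "random"):
            raise ValueError('age_sampling must be "stratified" or "random"')
        if self.age_space_group not in ("division", "strat", "set"):
            raise ValueError('age_space_group must be "division", "strat" or "set"')
        if self.age_length_group <= 0:
            raise ValueError("age_length_group must be > 0")
        if len(self.trawl_dim) != 2 or min(self.trawl_dim) <= 0:
            raise ValueError("trawl_dim must be two positive lengths (km)")

    @property
    def trawl_area(self) -> float:
        return float(self.trawl_dim[0]) * float(self.trawl_dim[1])

    def catchability(self, ages) -> np.ndarray:
        if self.q_table is not None:
            q = np.asarray(self.q_table, dtype=float)
            if q.shape != np.asarray(ages).shape:
                raise ValueError("q_table must supply one catchability per age")
            return q
        return logistic_catchability(ages, self.q_k, self.q_x0)


class _GridCache:
    """Per-survey precomputation of stratum membership and set allocations."""

    def __init__(self, grid: SurveyGrid, spec: SurveySpec):
        cells = grid.cells
        self.x = cells["x"].to_numpy(float)
        self.y = cells["y"].to_numpy(float)
        self.depth = cells["depth"].to_numpy(float)
        self.cell_id = cells["cell"].to_numpy()
        strat_codes, strat_ids = pd.factorize(cells["strat"], sort=True)
        self.strat_code = strat_codes
        self.strat_ids = np.asarray(strat_ids)
        self.n_strata = self.strat_ids.size
        self.division_of_cell = cells["division"].to_numpy()
        div_of_strat = cells.groupby("strat")["division"].first()
        self.div_of_strat = div_of_strat.loc[self.strat_ids].to_numpy()
        div_codes, div_ids = pd.factorize(pd.Series(self.div_of_strat), sort=True)
        self.div_code_of_strat = div_codes
        self.n_divisions = np.asarray(div_ids).size
        self.cells_of_strat = [np.flatnonzero(strat_codes == h) for h in range(self.n_strata)]
        counts = np.array([c.size for c in self.cells_of_strat])
        self.A_strat = counts * grid.cell_area
        if spec.trawl_area > grid.cell_area + 1e-12:
            raise ValueError("trawl area must not exceed the cell area")
        if spec.census:
            self.sets_per_strat = counts.copy()
        else:
            # round half away from zero, then apply the min_sets floor
            alloc = np.floor(self.A_strat * spec.set_den + 0.5).astype(int)
            self.sets_per_strat = np.maximum(spec.min_sets, alloc)
        self.n_sets_per_year = int(self.sets_per_strat.sum())


def _draw_sets(cache: _GridCache, n_years: int, rng: np.random.Generator, census: bool):
    """Cell and stratum indices for all sets of all years of one replicate."""
    per_year_strat = np.repeat(np.arange(cache.n_strata), cache.sets_per_strat)
    strat_idx = np.tile(per_year_strat, n_years)
    year_idx = np.repeat(np.arange(n_years), cache.n_sets_per_year)
    if census:
        per_year_cells = np.concatenate(cache.cells_of_strat)
        cell_idx = np.tile(per_year_cells, n_years)
        return year_idx, strat_idx, cell_idx
    picks = []
    for h in range(cache.n_strata):
        members = cache.cells_of_strat[h]
        k = cache.sets_per_strat[h]
        picks.append(members[rng.integers(0, members.size, size=(n_years, k))])
    # assemble year-major: for each year, strata in order
    cell_idx = np.concatenate([picks[h][y] for y in range(n_years)
                               for h in range(cache.n_strata)])
    return year_idx, strat_idx, cell_idx


def allocate_sets(grid: SurveyGrid, set_den: float = 2.0 / 1000.0, min_sets: int = 2,
                  seed=0, census: bool = False) -> pd.DataFrame:
    """Draw one year's stratified-random set locations as a table."""
    spec = SurveySpec(set_den=set_den, min_sets=min_sets, census=census)
    cache = _GridCache(grid, spec)
    rng = as_rng(seed, "allocation")
    _, strat_idx, cell_idx = _draw_sets(cache, 1, rng, census)
    return pd.DataFrame({
        "set": np.arange(1, strat_idx.size + 1),
        "division": cache.div_of_strat[strat_idx],
        "strat": cache.strat_ids[strat_idx],
        "cell": cache.cell_id[cell_idx],
        "x": cache.x[cell_idx],
        "y": cache.y[cell_idx],
        "depth": cache.depth[cell_idx],
    })


def _split_shared_cells(avail: np.ndarray, year_idx: np.ndarray, cell_idx: np.ndarray,
                        n_cells: int, rng: np.random.Generator) -> np.ndarray:
    """Partition cell abundance across co-located sets.

    k sets sharing a cell receive an equal-probability multinomial split of
    the cell's fish, and each then effectively tows its own sub-area
    A_cell / k, so its swept proportion scales by k (see the returned
    multiplier).  The per-set expected catch is then independent of k — the
    allocation stays design-unbiased — while the summed catch can never
    exceed the cell abundance.

    Returns the per-set proportion multiplier k.
    """
    key = year_idx.astype(np.int64) * n_cells + cell_idx
    order = np.argsort(key, kind="stable")
    ks = key[order]
    new = np.ones(ks.size, dtype=bool)
    new[1:] = ks[1:] != ks[:-1]
    starts = np.flatnonzero(new)
    counts = np.diff(np.append(starts, ks.size))
    mult = np.ones(key.size)
    for s, c in zip(starts[counts > 1], counts[counts > 1]):
        members = order[s:s + c]
        mult[members] = c
        p = np.full(c, 1.0 / c)
        for a in np.flatnonzero(avail[:, members[0]] > 0):
            avail[a, members] = rng.multinomial(avail[a, members[0]], p)
    return mult


def _rank_within(keys: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Uniform-random rank (0-based) of each element within its key group."""
    r = rng.random(keys.size)
    order = np.lexsort((r, keys))
    ks = keys[order]
    new = np.ones(ks.size, dtype=bool)
    if ks.size:
        new[1:] = ks[1:] != ks[:-1]
    grp = np.cumsum(new) - 1
    starts = np.flatnonzero(new)
    rank_sorted = np.arange(ks.size) - starts[grp]
    rank = np.empty(ks.size, dtype=np.int64)
    rank[order] = rank_sorted
    return rank


@dataclass(frozen=True)
class SurveyData:
    """Simulated survey: set records, fish-level samples, and true indices.

    ``I`` is the catchability-corrected true abundance q_a * N[a, y] (age x
    year); ``I_at_length`` its length-binned counterpart.  ``setdet`` has one
    row per set; ``samp`` one row per caught fish with measured/aged flags.
    """

    spec: SurveySpec
    spatial: SpatialPopulation = field(repr=False)
    setdet: pd.DataFrame = field(repr=False)
    samp: pd.DataFrame = field(repr=False)
    I: np.ndarray = field(repr=False)
    I_at_length: np.ndarray = field(repr=False)
    q: np.ndarray = field(repr=False)


def _simulate_one(spatial: SpatialPopulation, spec: SurveySpec, cache: _GridCache,
                  N_cells: np.ndarray, p_catch: np.ndarray, edges: np.ndarray,
                  rng: np.random.Generator):
    """One survey replicate; returns compact per-set and per-fish arrays."""
    pop = spatial.population
    n_years = pop.years.size
    n_cells = spatial.grid.n_cells

    # stochastic rounding of fractional cell abundances: floor + Bernoulli of
    # the fractional part, so E[rounded] equals the continuous abundance and
    # rare (sub-unit) ages are not systematically zeroed out
    lo = np.floor(N_cells)
    Nint = (lo + (rng.random(N_cells.shape) < N_cells - lo)).astype(np.int64)

    year_idx, strat_idx, cell_idx = _draw_sets(cache, n_years, rng, spec.census)
    n_sets = year_idx.size

    avail = Nint[:, year_idx, cell_idx].copy()  # (A, n_sets)
    mult = _split_shared_cells(avail, year_idx, cell_idx, n_cells, rng)
    p_eff = np.clip(p_catch[:, None] * mult[None, :], 0.0, 1.0)
    catch = rng.binomial(avail, p_eff)  # (A, n_sets)
    n_i = catch.sum(axis=0)

    # expand to individual fish, set-major then age-major within a set
    flat = catch.T.ravel()
    pair = np.repeat(np.arange(flat.size), flat)
    f_set = pair // pop.ages.size
    f_age = pair % pop.ages.size
    lengths = pop.growth.sample_lengths(pop.ages[f_age], rng, edges)

    # length measurement: up to lengths_cap per set, uniform without replacement
    rank_len = _rank_within(f_set, rng)
    measured = rank_len < spec.lengths_cap

    # ageing
    aged = np.zeros(f_set.size, dtype=bool)
    mi = np.flatnonzero(measured)
    if mi.size:
        if spec.age_sampling == "random":
            keys = f_set[mi]
        else:
            ab = np.ceil(lengths[mi] / spec.age_length_group - 1e-9).astype(np.int64)
            n_ab = int(ab.max()) + 1 if ab.size else 1
            if spec.age_space_group == "set":
                unit = f_set[mi]
                keys = unit * n_ab + ab
            else:
                if spec.age_space_group == "division":
                    unit = cache.div_code_of_strat[strat_idx][f_set[mi]]
                    n_unit = cache.n_divisions
                else:
                    unit = strat_idx[f_set[mi]]
                    n_unit = cache.n_strata
                keys = (year_idx[f_set[mi]] * n_unit + unit) * n_ab + ab
        rank_age = _rank_within(keys, rng)
        aged[mi] = rank_age < spec.ages_cap

    sets = {"year_idx": year_idx, "strat_idx": strat_idx, "cell_idx": cell_idx, "n": n_i}
    fish = {"set_row": f_set, "age_idx": f_age, "length": lengths,
            "measured": measured, "aged": aged}
    return sets, fish


def sim_survey(spatial: SpatialPopulation, spec: SurveySpec | None = None,
               seed: int = 0, first_sim: int = 0, stream: int = 0) -> SurveyData:
    """Simulate ``spec.n_sims`` independent replicate surveys of a population.

    ``first_sim`` offsets replicate ids (and their random substreams) so a run
    split into batches reproduces a single unbatched run; ``stream`` separates
    the substreams of different survey designs sharing one root seed.
    """
    spec = spec if spec is not None else SurveySpec()
    pop = spatial.population
    cache = _GridCache(spatial.grid, spec)
    N_cells = spatial.abundance
    q = spec.catchability(pop.ages)
    p_catch = (spec.trawl_area / spatial.grid.cell_area) * q
    if np.any(p_catch > 1 + 1e-12):
        raise ValueError("catch probability exceeds 1; shrink the trawl or q")
    p_catch = np.clip(p_catch, 0.0, 1.0)
    edges = pop.length_edges

    set_frames, fish_frames = [], []
    for s in range(spec.n_sims):
        sim_id = first_sim + s
        rng = as_rng(seed, "survey", stream, sim_id)
        sets, fish = _simulate_one(spatial, spec, cache, N_cells, p_catch, edges, rng)
        n_sets = sets["year_idx"].size
        set_frames.append(pd.DataFrame({
            "sim": np.full(n_sets, sim_id + 1, dtype=np.int32),
            "year": pop.years[sets["year_idx"]],
            "division": cache.div_of_strat[sets["strat_idx"]],
            "strat": cache.strat_ids[sets["strat_idx"]],
            "set": np.arange(1, n_sets + 1, dtype=np.int32),
            "cell": cache.cell_id[sets["cell_idx"]],
            "x": cache.x[sets["cell_idx"]],
            "y": cache.y[sets["cell_idx"]],
            "depth": cache.depth[sets["cell_idx"]],
            "n": sets["n"].astype(np.int64),
        }))
        nf = fish["set_row"].size
        fish_frames.append(pd.DataFrame({
            "sim": np.full(nf, sim_id + 1, dtype=np.int32),
            "year": pop.years[sets["year_idx"]][fish["set_row"]],
            "set": (fish["set_row"] + 1).astype(np.int32),
            "fish": np.arange(1, nf + 1, dtype=np.int64),
            "age": pop.ages[fish["age_idx"]],
            "length": fish["length"].astype(np.float32),
            "measured": fish["measured"],
            "aged": fish["aged"],
        }))

    I = q[:, None] * pop.N
    I_at_length = pop.phi.T @ I
    return SurveyData(spec=spec, spatial=spatial,
                      setdet=pd.concat(set_frames, ignore_index=True),
                      samp=pd.concat(fish_frames, ignore_index=True),
                      I=I, I_at_length=I_at_length, q=q)
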