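"""Distributing the aggregate population over the survey grid.

Cell shares are driven by a log-scale depth preference (a parabola peaking at
mu_d) plus a zero-mean Gaussian field xi with separable covariance

    sigma_xi^2 * AR1(age; phi_age) (x) AR1(year; phi_year) (x) Matern(space)

The shares eta = exp(depth_effect + xi) are normalized per (age, year) so the
cell abundances sum exactly to the cohort-model abundance: the spatial step
redistributes fish, it never creates or destroys them.

The spatial factor uses the Matern correlation with smoothness lambda and
scale kappa = sqrt(8 * lambda) / range, so correlation has dropped to ~0.14
at the range distance.  Fields are sampled exactly by dense Cholesky of the
cell-to-cell correlation matrix; this is intended for grids up to a few
thousand cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn
from scipy.special import kv

from ._rng import as_rng
from .grid import SurveyGrid
from .population import Population, ar1_corr

__all__ = ["FieldParams", "DepthPrefParams", "SpatialPopulation",
           "matern_correlation", "simulate_ays_field", "depth_effect",
           "distribute_population", "sim_distribution", "save_spatial",
           "load_spatial"]


@dataclass(frozen=True)
class FieldParams:
    """Space-age-year noise parameters.

    sd is the marginal SD of the field on the log scale; corr_range the
    distance (km) at which spatial correlation becomes small; lambda_ the
    Matern smoothness.  group_ages / group_years list indices whose field
    slices are shared (one realization for the whole group).
    """

    sd: float = 2.8
    corr_range: float = 300.0
    lambda_: float = 1.0
    phi_age: float = 0.5
    phi_year: float = 0.9
    group_ages: Optional[Sequence[int]] = tuple(range(5, 21))
    group_years: Optional[Sequence[int]] = None

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.corr_range <= 0:
            raise ValueError("corr_range must be > 0")
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be > 0")
        if not (abs(self.phi_age) < 1 and abs(self.phi_year) < 1):
            raise ValueError("|phi| must be < 1")


@dataclass(frozen=True)
class DepthPrefParams:
    """Parabolic (log-scale Gaussian) depth preference: peak at mu_d, width sigma_d."""

    mu_d: float = 200.0
    sigma_d: float = 70.0

    def __post_init__(self):
        if self.sigma_d <= 0:
            raise ValueError("sigma_d must be > 0")


def matern_correlation(distance, corr_range: float = 300.0, lambda_: float = 1.0):
    """Matern correlation at the given distance(s); 1 at zero lag."""
    d = np.asarray(distance, dtype=float)
    kappa = np.sqrt(8.0 * lambda_) / corr_range
    x = kappa * d
    out = np.empty_like(x)
    zero = x <= 0
    with np.errstate(invalid="ignore", over="ignore"):
        val = (2.0 ** (1.0 - lambda_) / gamma_fn(lambda_)) * x ** lambda_ * kv(lambda_, x)
    out[~zero] = val[~zero]
    out[zero] = 1.0
    # kv underflows to 0 for large arguments -> correlation 0
    np.nan_to_num(out, copy=False)
    return out if out.ndim else float(out)


def depth_effect(depth, pref: DepthPrefParams):
    """Log-scale depth preference: -(d - mu_d)^2 / (2 sigma_d^2); max 0 at mu_d."""
    d = np.asarray(depth, dtype=float)
    return -((d - pref.mu_d) ** 2) / (2.0 * pref.sigma_d ** 2)


def _group_blocks(values: np.ndarray, group: Optional[Sequence[int]]):
    """Map each index to a block; grouped values share one block.

    Returns (block_of_index, representative_values_per_block).
    """
    values = np.asarray(values)
    if group is None or len(group) == 0:
        return np.arange(values.size), values.astype(float)
    group = set(group)
    if not group.issubset(set(values.tolist())):
        raise ValueError(f"group members {sorted(group - set(values.tolist()))} "
                         "are outside the index set")
    blocks = []
    block_of = np.empty(values.size, dtype=int)
    reps = []
    group_block = None
    for i, v in enumerate(values.tolist()):
        if v in group:
            if group_block is None:
                group_block = len(reps)
                reps.append(float(v))
            block_of[i] = group_block
        else:
            block_of[i] = len(reps)
            reps.append(float(v))
    return block_of, np.asarray(reps)


def _ar1_corr_at(values: np.ndarray, phi: float) -> np.ndarray:
    """AR1 correlation phi**|vi - vj| between (possibly non-contiguous) indices."""
    if phi == 0:
        return np.eye(values.size)
    lag = np.abs(values[:, None] - values[None, :]).round().astype(int)
    return np.sign(phi) ** lag * np.abs(phi) ** lag


def simulate_ays_field(grid: SurveyGrid, ages, years, params: FieldParams | None = None,
                       seed=0) -> np.ndarray:
    """Sample the zero-mean age x year x cell Gaussian field xi.

    Exact sampling: Cholesky factors of the age/year AR1 and spatial Matern
    correlation matrices applied to iid normals along each axis.  Ages (years)
    inside group_ages (group_years) share one realization, simulated at the
    group's first index and broadcast.
    """
    p = params if params is not None else FieldParams()
    ages = np.asarray(ages)
    years = np.asarray(years)
    rng = as_rng(seed, "field")
    S = grid.n_cells
    if p.sd == 0:
        return np.zeros((ages.size, years.size, S))

    a_block, a_reps = _group_blocks(ages, p.group_ages)
    y_block, y_reps = _group_blocks(years, p.group_years)

    xy = grid.cells[["x", "y"]].to_numpy()
    diff = xy[:, None, :] - xy[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    C_s = matern_correlation(dist, p.corr_range, p.lambda_)
    # tiny jitter guards Cholesky against numerically semidefinite matrices
    L_s = np.linalg.cholesky(C_s + 1e-10 * np.eye(S))
    L_a = np.linalg.cholesky(_ar1_corr_at(a_reps, p.phi_age) + 1e-12 * np.eye(a_reps.size))
    L_y = np.linalg.cholesky(_ar1_corr_at(y_reps, p.phi_year) + 1e-12 * np.eye(y_reps.size))

    g = rng.standard_normal((a_reps.size, y_reps.size, S))
    x = np.tensordot(L_a, g, axes=(1, 0))            # age axis
    x = np.tensordot(L_y, x, axes=(1, 1)).transpose(1, 0, 2)  # year axis
    x = np.tensordot(x, L_s, axes=(2, 1))            # space axis
    xi = p.sd * x
    return xi[a_block][:, y_block, :]


@dataclass(frozen=True)
class SpatialPopulation:
    """Population resolved to age x year x cell, linked to its grid."""

    population: Population
    grid: SurveyGrid
    abundance: np.ndarray = field(repr=False)  # (n_ages, n_years, n_cells)

    @property
    def grid_xy(self) -> pd.DataFrame:
        return self.grid.cells

    @property
    def sp_N(self) -> pd.DataFrame:
        """Long-format cell abundance table (age, year, cell, N)."""
        ages = self.population.ages
        years = self.population.years
        cells = self.grid.cells["cell"].to_numpy()
        A, Y, S = self.abundance.shape
        return pd.DataFrame({
            "age": np.repeat(ages, Y * S),
            "year": np.tile(np.repeat(years, S), A),
            "cell": np.tile(cells, A * Y),
            "N": self.abundance.ravel(),
        })


def distribute_population(population: Population, grid: SurveyGrid,
                          field_params: FieldParams | None = None,
                          depth_pref: DepthPrefParams | None = None,
                          seed=0) -> SpatialPopulation:
    """Split N[a, y] across cells by normalized shares eta = exp(depth effect + xi)."""
    fp = field_params if field_params is not None else FieldParams()
    dp = depth_pref if depth_pref is not None else DepthPrefParams()
    xi = simulate_ays_field(grid, population.ages, population.years, fp, seed)
    log_eta = depth_effect(grid.cells["depth"].to_numpy(), dp)[None, None, :] + xi
    # normalize in a numerically safe way before exponentiating
    log_eta -= log_eta.max(axis=2, keepdims=True)
    eta = np.exp(log_eta)
    shares = eta / eta.sum(axis=2, keepdims=True)
    ab = population.N[:, :, None] * shares
    return SpatialPopulation(population=population, grid=grid, abundance=ab)


def save_spatial(spatial: SpatialPopulation, outdir) -> None:
    """Persist a SpatialPopulation: population CSVs, grid CSV, abundance array."""
    from pathlib import Path
    from .grid import save_grid
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    spatial.population.save(out / "population")
    save_grid(spatial.grid, out / "grid.csv")
    np.save(out / "abundance.npy", spatial.abundance)


def load_spatial(indir) -> SpatialPopulation:
    from pathlib import Path
    from .grid import load_grid
    from .population import load_population
    src = Path(indir)
    pop = load_population(src / "population")
    grid = load_grid(src / "grid.csv")
    ab = np.load(src / "abundance.npy")
    if ab.shape != (pop.ages.size, pop.years.size, grid.n_cells):
        raise ValueError("abundance array does not match population/grid dimensions")
    return SpatialPopulation(population=pop, grid=grid, abundance=ab)


def sim_distribution(population: Population, grid: SurveyGrid | None = None,
                     field_params: FieldParams | None = None,
                     depth_pref: DepthPrefParams | None = None,
                     seed=0) -> SpatialPopulation:
    """Orchestrate grid + field + depth preference into a SpatialPopulation."""
    from .grid import make_grid
    g = grid if grid is not None else make_grid()
    return distribute_population(population, g, field_params, depth_pref, seed)
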