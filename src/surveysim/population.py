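"""Aggregate age-structured population simulation.

The population model is an exponential-decay cohort model:

    N[a, y] = N[a-1, y-1] * exp(-Z[a-1, y-1])

with recruitment (age-1 abundance) following a lognormal random walk around a
baseline, total mortality following a lognormal baseline plus a separable 2-D
AR1 (age x year) process error, and growth following the von Bertalanffy curve
with lognormal length-at-age.  Abundance-at-age is spread over discrete length
bins through the probability matrix phi[a, l] = P(length in bin l | age a).

No plus group is modelled; extend the age vector instead.  No stock-recruit
relationship is implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._rng import as_rng

__all__ = [
    "PopulationParams",
    "VonBGrowth",
    "Population",
    "simulate_recruitment",
    "simulate_total_mortality",
    "simulate_cohorts",
    "vonB_mean_length",
    "length_given_age_probs",
    "sim_abundance",
    "ar1_corr",
]


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class PopulationParams:
    """Parameters of the aggregate population (defaults: a generic long-lived groundfish).

    mu_r is the mean recruitment on the natural scale (fish); sigma_r the SD of
    the log-recruitment random-walk increments.  mu_Z is mean total mortality
    (per year) and sigma_delta / phi_delta_* control the SD and age/year lag-1
    correlations of the log-mortality process error.  Growth is von
    Bertalanffy with lognormal scatter sigma_L, binned at length_group cm.
    mu_r may be a per-year vector and mu_Z an age x year matrix.
    """

    ages: tuple = tuple(range(1, 21))
    years: tuple = tuple(range(1, 21))
    mu_r: float = 30_000_000.0
    sigma_r: float = 0.5
    mu_Z: float = 0.5
    sigma_delta: float = 0.2
    phi_delta_age: float = 0.9
    phi_delta_year: float = 0.5
    Linf: float = 120.0
    L0: float = 5.0
    K: float = 0.1
    sigma_L: float = 0.1
    length_group: float = 3.0

    def __post_init__(self):
        ages = np.asarray(self.ages)
        years = np.asarray(self.years)
        _check(ages.size > 0 and years.size > 0, "ages and years must be non-empty")
        _check(ages.size == 1 or np.all(np.diff(ages) == 1), "ages must increase with step 1")
        _check(years.size == 1 or np.all(np.diff(years) == 1), "years must increase with step 1")
        mu_r = np.asarray(self.mu_r, dtype=float)
        _check(np.all(mu_r > 0), "mu_r must be > 0")
        _check(mu_r.ndim == 0 or mu_r.shape == (years.size,),
               "vector mu_r must have one entry per year")
        _check(self.sigma_r >= 0, "sigma_r must be >= 0")
        mu_Z = np.asarray(self.mu_Z, dtype=float)
        _check(np.all(mu_Z > 0), "mu_Z must be > 0")
        _check(mu_Z.ndim == 0 or mu_Z.shape == (ages.size, years.size),
               "matrix mu_Z must be ages x years")
        _check(self.sigma_delta >= 0, "sigma_delta must be >= 0")
        for name in ("phi_delta_age", "phi_delta_year"):
            _check(abs(getattr(self, name)) < 1, f"|{name}| must be < 1")
        _check(self.Linf > self.L0 >= 0, "need Linf > L0 >= 0")
        _check(self.K > 0, "K must be > 0")
        _check(self.sigma_L >= 0, "sigma_L must be >= 0")
        _check(self.length_group > 0, "length_group must be > 0")


def vonB_mean_length(age, Linf: float = 120.0, L0: float = 5.0, K: float = 0.1):
    """Mean length at age: Linf - (Linf - L0) * exp(-K * age)."""
    _check(Linf > L0, "need Linf > L0")
    _check(K > 0, "K must be > 0")
    return Linf - (Linf - L0) * np.exp(-K * np.asarray(age, dtype=float))


@dataclass(frozen=True)
class VonBGrowth:
    """Length-given-age law: lognormal around the von Bertalanffy mean.

    Retained inside the population object so the survey step can assign
    lengths to caught fish with exactly the law that generated the
    abundance-at-length matrix.
    """

    Linf: float = 120.0
    L0: float = 5.0
    K: float = 0.1
    sigma_L: float = 0.1
    length_group: float = 3.0

    def mean_length(self, age):
        return vonB_mean_length(age, self.Linf, self.L0, self.K)

    def length_edges(self, ages) -> np.ndarray:
        """Bin edges from 0 to 10x the maximum predicted mean length.

        Bins are left-open/right-closed, width length_group; the top edge is
        rounded up to a multiple of the bin width.
        """
        max_len = float(np.max(self.mean_length(ages)))
        top = np.ceil(10.0 * max_len / self.length_group) * self.length_group
        n = int(round(top / self.length_group))
        return np.arange(n + 1, dtype=float) * self.length_group

    def probs(self, ages) -> np.ndarray:
        """phi[a, l] = P(length in bin l | age a); rows sum to 1 exactly."""
        ages = np.asarray(ages)
        edges = self.length_edges(ages)
        mu = self.mean_length(ages)[:, None]
        if self.sigma_L == 0:
            # degenerate: all mass in the bin containing the mean
            idx = np.searchsorted(edges, mu.ravel(), side="left") - 1
            idx = np.clip(idx, 0, edges.size - 2)
            phi = np.zeros((ages.size, edges.size - 1))
            phi[np.arange(ages.size), idx] = 1.0
            return phi
        with np.errstate(divide="ignore"):
            log_edges = np.log(edges)  # log(0) = -inf -> CDF 0 at the left end
        z = (log_edges[None, :] - np.log(mu)) / self.sigma_L
        cdf = norm.cdf(z)
        cdf[:, -1] = 1.0  # top bin absorbs the upper tail
        return np.diff(cdf, axis=1)

    def bin_lengths(self, lengths: np.ndarray, edges: np.ndarray) -> np.ndarray:
        """Map raw lengths to bin labels (upper edges), clipping into the top bin."""
        idx = np.searchsorted(edges, lengths, side="left") - 1
        idx = np.clip(idx, 0, edges.size - 2)
        return edges[idx + 1]

    def sample_lengths(self, ages, rng: np.random.Generator, edges: np.ndarray | None = None):
        """Draw binned lengths for fish of the given (true) ages."""
        ages = np.asarray(ages, dtype=float)
        if edges is None:
            edges = self.length_edges(np.unique(ages) if ages.size else [1.0])
        mu = self.mean_length(ages)
        if self.sigma_L == 0:
            raw = mu
        else:
            raw = np.exp(np.log(mu) + rng.normal(0.0, self.sigma_L, size=ages.shape))
        return self.bin_lengths(raw, edges)


def length_given_age_probs(age, growth: VonBGrowth, length_edges=None) -> np.ndarray:
    """Probability vector over length bins for one age (or matrix for several)."""
    ages = np.atleast_1d(np.asarray(age))
    if length_edges is not None:
        edges = np.asarray(length_edges, dtype=float)
        widths = np.diff(edges)
        if edges[0] != 0 or not np.allclose(widths, growth.length_group):
            raise ValueError("length bins must be contiguous, start at 0, width length_group")
    phi = growth.probs(ages)
    return phi[0] if np.isscalar(age) or np.ndim(age) == 0 else phi


def simulate_recruitment(years, mu_r, sigma_r, seed=0) -> np.ndarray:
    """Recruitment series: log(R_y) = log(mu_r) + eps_y, eps a Gaussian random walk.

    eps_0 = 0, so year-1 recruitment is a draw centred on log(mu_r).
    """
    years = np.asarray(years)
    mu_r = np.broadcast_to(np.asarray(mu_r, dtype=float), years.shape)
    _check(np.all(mu_r > 0), "mu_r must be > 0")
    _check(sigma_r >= 0, "sigma_r must be >= 0")
    rng = as_rng(seed, "recruitment")
    eps = np.cumsum(rng.normal(0.0, sigma_r, size=years.size))
    return np.exp(np.log(mu_r) + eps)


def ar1_corr(n: int, phi: float) -> np.ndarray:
    """AR1 correlation matrix rho[i, j] = phi**|i-j|."""
    idx = np.arange(n)
    return phi ** np.abs(idx[:, None] - idx[None, :])


def simulate_total_mortality(ages, years, mu_Z, sigma_delta, phi_age, phi_year,
                             seed=0) -> np.ndarray:
    """Total mortality matrix: log(Z) = log(mu_Z) + delta.

    delta is a stationary separable 2-D AR1 Gaussian process with marginal
    variance sigma_delta**2, sampled exactly via the Cholesky factors of the
    two AR1 correlation matrices (age x year Kronecker structure).
    """
    ages, years = np.asarray(ages), np.asarray(years)
    _check(abs(phi_age) < 1 and abs(phi_year) < 1, "|phi| must be < 1")
    _check(sigma_delta >= 0, "sigma_delta must be >= 0")
    mu_Z = np.broadcast_to(np.asarray(mu_Z, dtype=float), (ages.size, years.size))
    _check(np.all(mu_Z > 0), "mu_Z must be > 0")
    rng = as_rng(seed, "mortality")
    if sigma_delta == 0:
        delta = np.zeros((ages.size, years.size))
    else:
        La = np.linalg.cholesky(ar1_corr(ages.size, phi_age))
        Ly = np.linalg.cholesky(ar1_corr(years.size, phi_year))
        g = rng.standard_normal((ages.size, years.size))
        delta = sigma_delta * (La @ g @ Ly.T)
    return np.exp(np.log(mu_Z) + delta)


def simulate_cohorts(R: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Fill the age x year abundance matrix by cohort decay.

    First row is recruitment; the first year's column is filled downward by
    exponential decay; interior cells follow their cohort diagonal.
    """
    R, Z = np.asarray(R, dtype=float), np.asarray(Z, dtype=float)
    A, Y = Z.shape
    _check(R.shape == (Y,), "R must have one entry per year (Z columns)")
    N = np.empty((A, Y))
    N[0, :] = R
    for a in range(1, A):
        N[a, 0] = N[a - 1, 0] * np.exp(-Z[a - 1, 0])
    for y in range(1, Y):
        N[1:, y] = N[:-1, y - 1] * np.exp(-Z[:-1, y - 1])
    return N


@dataclass(frozen=True)
class Population:
    """Simulated aggregate population: cohort matrices plus the growth law."""

    params: PopulationParams
    R: np.ndarray              # recruitment by year
    N0: np.ndarray             # abundance at age, first year
    Z: np.ndarray              # total mortality, age x year
    N: np.ndarray              # abundance, age x year
    lengths: np.ndarray        # length-bin upper edges (labels)
    length_edges: np.ndarray   # bin edges incl. 0
    phi: np.ndarray            # P(length bin | age), age x length
    N_at_length: np.ndarray    # abundance, length x year
    growth: VonBGrowth = field(repr=False, default_factory=VonBGrowth)

    @property
    def ages(self) -> np.ndarray:
        return np.asarray(self.params.ages)

    @property
    def years(self) -> np.ndarray:
        return np.asarray(self.params.years)

    def save(self, outdir) -> None:
        """Write N/Z/R/N_at_length as CSV tables (age/year/length headers) plus
        the parameter echo as YAML."""
        import yaml
        from dataclasses import asdict
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        years = [str(y) for y in self.years]
        pd.DataFrame(self.N, index=self.ages, columns=years).rename_axis("age") \
            .to_csv(out / "N.csv")
        pd.DataFrame(self.Z, index=self.ages, columns=years).rename_axis("age") \
            .to_csv(out / "Z.csv")
        pd.DataFrame({"year": self.years, "R": self.R}).to_csv(out / "R.csv", index=False)
        pd.DataFrame(self.N_at_length, index=self.lengths, columns=years) \
            .rename_axis("length").to_csv(out / "N_at_length.csv")
        params = {k: (list(v) if isinstance(v, tuple) else v)
                  for k, v in asdict(self.params).items()}
        (out / "params.yaml").write_text(yaml.safe_dump(params, sort_keys=True))


def load_population(indir) -> Population:
    """Rebuild a Population from a directory written by ``Population.save``."""
    import yaml
    src = Path(indir)
    raw = yaml.safe_load((src / "params.yaml").read_text())
    raw = {k: (tuple(v) if isinstance(v, list) else v) for k, v in raw.items()}
    p = PopulationParams(**raw)
    N = pd.read_csv(src / "N.csv", index_col=0).to_numpy(float)
    Z = pd.read_csv(src / "Z.csv", index_col=0).to_numpy(float)
    R = pd.read_csv(src / "R.csv")["R"].to_numpy(float)
    growth = VonBGrowth(p.Linf, p.L0, p.K, p.sigma_L, p.length_group)
    edges = growth.length_edges(np.asarray(p.ages))
    phi = growth.probs(np.asarray(p.ages))
    return Population(params=p, R=R, N0=N[:, 0].copy(), Z=Z, N=N,
                      lengths=edges[1:].copy(), length_edges=edges, phi=phi,
                      N_at_length=phi.T @ N, growth=growth)


def sim_abundance(params: PopulationParams | None = None, seed: int = 0) -> Population:
    """Simulate the aggregate population (recruitment, mortality, cohorts, lengths)."""
    p = params if params is not None else PopulationParams()
    R = simulate_recruitment(p.years, p.mu_r, p.sigma_r, seed)
    Z = simulate_total_mortality(p.ages, p.years, p.mu_Z, p.sigma_delta,
                                 p.phi_delta_age, p.phi_delta_year, seed)
    N = simulate_cohorts(R, Z)
    growth = VonBGrowth(p.Linf, p.L0, p.K, p.sigma_L, p.length_group)
    edges = growth.length_edges(np.asarray(p.ages))
    phi = growth.probs(np.asarray(p.ages))
    N_at_length = phi.T @ N
    return Population(params=p, R=R, N0=N[:, 0].copy(), Z=Z, N=N,
                      lengths=edges[1:].copy(), length_edges=edges, phi=phi,
                      N_at_length=N_at_length, growth=growth)
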