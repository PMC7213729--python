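"""YAML configuration schema and the end-to-end pipeline runner.

A run configuration has sections ``population``, ``grid``, ``field``,
``depth_pref``, ``survey`` and ``strat`` plus a ``seed``; every omitted key
falls back to the package defaults, so an empty file is a complete default
configuration.  Unknown keys are rejected with their full path.  ``ages`` and
``years`` are written as inclusive [first, last] ranges.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .distribution import DepthPrefParams, FieldParams, distribute_population
from .grid import GridParams, SurveyGrid, load_grid, make_grid, save_grid
from .population import PopulationParams, sim_abundance
from .stratified import StratOptions, run_strat, strat_error
from .survey import SurveySpec, sim_survey

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config",
           "config_from_dict", "config_to_dict", "config_hash", "run_pipeline"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    population: PopulationParams = field(default_factory=PopulationParams)
    grid: Union[GridParams, str] = field(default_factory=GridParams)
    field_params: FieldParams = field(default_factory=FieldParams)
    depth_pref: DepthPrefParams = field(default_factory=DepthPrefParams)
    survey: SurveySpec = field(default_factory=SurveySpec)
    strat: StratOptions = field(default_factory=StratOptions)
    seed: int = 0


# YAML key -> dataclass field translations per section
_ALIASES = {
    "field": {"range": "corr_range", "lambda": "lambda_"},
    "survey": {},
    "population": {},
    "grid": {},
    "depth_pref": {"mu": "mu_d", "sigma": "sigma_d"},
    "strat": {},
}
_SECTIONS = ("population", "grid", "field", "depth_pref", "survey", "strat")


def _expand_range(val, what: str):
    if val is None:
        return None
    if not isinstance(val, (list, tuple)):
        raise ConfigError(f"{what} must be an inclusive [first, last] range")
    if len(val) != 2 or val[1] < val[0]:
        raise ConfigError(f"{what} must be an inclusive [first, last] range")
    return tuple(range(int(val[0]), int(val[1]) + 1))


def _build(cls, data: dict, section: str):
    aliases = _ALIASES.get(section, {})
    valid = set(cls.__dataclass_fields__)
    kwargs = {}
    for key, val in data.items():
        name = aliases.get(key, key)
        if name not in valid:
            raise ConfigError(f"unknown key '{section}.{key}'")
        kwargs[name] = val
    for tup in ("trawl_dim", "x_range", "y_range", "res", "depth_range",
                "strat_breaks", "q_table"):
        if kwargs.get(tup) is not None:
            kwargs[tup] = tuple(kwargs[tup])
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section '{section}': {exc}") from exc


def config_from_dict(data: Optional[dict]) -> RunConfig:
    data = dict(data or {})
    unknown = set(data) - set(_SECTIONS) - {"seed", "out"}
    if unknown:
        raise ConfigError(f"unknown key(s): {', '.join(sorted(unknown))}")

    pop_raw = dict(data.get("population") or {})
    for key in ("ages", "years"):
        if key in pop_raw:
            pop_raw[key] = _expand_range(pop_raw[key], f"population.{key}")
    population = _build(PopulationParams, pop_raw, "population")

    grid_raw = data.get("grid")
    if isinstance(grid_raw, str):
        grid: Union[GridParams, str] = grid_raw
    else:
        grid = _build(GridParams, dict(grid_raw or {}), "grid")

    field_raw = dict(data.get("field") or {})
    for key in ("group_ages", "group_years"):
        if key in field_raw:
            field_raw[key] = _expand_range(field_raw[key], f"field.{key}")
    fp = _build(FieldParams, field_raw, "field")

    dp = _build(DepthPrefParams, dict(data.get("depth_pref") or {}), "depth_pref")

    sv_raw = dict(data.get("survey") or {})
    q = sv_raw.pop("q", None)
    if q is not None:
        extra = set(q) - {"k", "x0"}
        if extra:
            raise ConfigError(f"unknown key(s) in survey.q: {', '.join(sorted(extra))}")
        if "k" in q:
            sv_raw["q_k"] = q["k"]
        if "x0" in q:
            sv_raw["q_x0"] = q["x0"]
    survey = _build(SurveySpec, sv_raw, "survey")

    strat = _build(StratOptions, dict(data.get("strat") or {}), "strat")
    return RunConfig(population=population, grid=grid, field_params=fp,
                     depth_pref=dp, survey=survey, strat=strat,
                     seed=int(data.get("seed", 0)))


def _contig(seq) -> list:
    return [int(seq[0]), int(seq[-1])]


def config_to_dict(cfg: RunConfig) -> dict:
    pop = asdict(cfg.population)
    pop["ages"] = _contig(cfg.population.ages)
    pop["years"] = _contig(cfg.population.years)
    fieldd = asdict(cfg.field_params)
    fieldd["range"] = fieldd.pop("corr_range")
    fieldd["lambda"] = fieldd.pop("lambda_")
    for key in ("group_ages", "group_years"):
        if fieldd[key] is not None:
            fieldd[key] = _contig(fieldd[key])
    svd = asdict(cfg.survey)
    svd["q"] = {"k": svd.pop("q_k"), "x0": svd.pop("q_x0")}
    grid = cfg.grid if isinstance(cfg.grid, str) else asdict(cfg.grid)
    out = {
        "population": pop,
        "grid": grid,
        "field": fieldd,
        "depth_pref": asdict(cfg.depth_pref),
        "survey": svd,
        "strat": asdict(cfg.strat),
        "seed": int(cfg.seed),
    }

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return [_clean(v) for v in obj]
        return obj

    return _clean(out)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return config_from_dict(raw)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config_to_dict(cfg), sort_keys=True).encode()).hexdigest()


def resolve_grid(cfg: RunConfig) -> SurveyGrid:
    if isinstance(cfg.grid, str):
        return load_grid(cfg.grid)
    return make_grid(cfg.grid)


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """simulate -> distribute -> survey -> stratified analysis -> error, with
    every table written to ``outdir`` and a manifest describing the run."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages = {}

    def stage(name, fn):
        t0 = time.monotonic()
        res = fn()
        stages[name] = round(time.monotonic() - t0, 3)
        logger.info("stage %-12s %.2fs", name, stages[name])
        return res

    pop = stage("abundance", lambda: sim_abundance(cfg.population, cfg.seed))
    grid = stage("grid", lambda: resolve_grid(cfg))
    spatial = stage("distribute", lambda: distribute_population(
        pop, grid, cfg.field_params, cfg.depth_pref, cfg.seed))
    sv = stage("survey", lambda: sim_survey(spatial, cfg.survey, cfg.seed))
    est = stage("strat", lambda: run_strat(sv, cfg.strat))
    err = stage("error", lambda: strat_error(est, sv))

    pop.save(out / "population")
    save_grid(grid, out / "grid.csv")
    sv.setdet.to_csv(out / "setdet.csv", index=False)
    sv.samp.to_csv(out / "samp.csv", index=False)
    est.total_strat.to_csv(out / "total_strat.csv", index=False)
    est.length_strat.to_csv(out / "length_strat.csv", index=False)
    est.age_strat.to_csv(out / "age_strat.csv", index=False)
    for kind in ("total", "length", "age"):
        getattr(err, f"{kind}_strat_error").to_csv(
            out / f"{kind}_strat_error.csv", index=False)
        getattr(err, f"{kind}_strat_error_stats").to_csv(
            out / f"{kind}_strat_error_stats.csv", index=False)
    save_config(cfg, out / "config.yaml")
    manifest = {"config_hash": config_hash(cfg), "seed": int(cfg.seed),
                "stage_seconds": stages}
    try:
        from importlib.metadata import version
        manifest["surveysim_version"] = version("surveysim")
    except Exception:
        pass
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"population": pop, "grid": grid, "spatial": spatial, "survey": sv,
            "estimates": est, "error": err, "outdir": out}
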