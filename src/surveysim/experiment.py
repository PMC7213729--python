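"""Factorial survey-design testing.

``expand_surveys`` builds the Cartesian product of candidate set densities
and length/age sub-sampling caps; ``test_surveys`` simulates, analyses and
scores every design over one fixed spatial population, so designs are
compared on identical truth.  Replication is split into ``n_loops`` batches
of ``n_sims`` replicates purely as a memory knob: every replicate draws its
random substream from (seed, design id, replicate id), so results are
bit-identical for any n_sims/n_loops split or worker count.

With ``export_dir`` set, per-(design, loop) error tables are checkpointed as
CSV next to a JSON manifest; ``resume_test`` completes an interrupted run and
returns results identical to an uninterrupted one.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .distribution import SpatialPopulation, load_spatial, save_spatial
from .stratified import StratOptions, _error_metrics, run_strat, strat_error
from .survey import SurveySpec, sim_survey

__all__ = ["expand_surveys", "test_surveys", "resume_test", "TestResults"]

logger = logging.getLogger(__name__)

_KINDS = ("total", "length", "age")


def expand_surveys(set_den=(2.0 / 1000.0,), lengths_cap=(500,), ages_cap=(10,)) \
        -> pd.DataFrame:
    """All combinations of the supplied vectors, set_den varying slowest."""
    for name, v in (("set_den", set_den), ("lengths_cap", lengths_cap),
                    ("ages_cap", ages_cap)):
        if len(tuple(v)) == 0:
            raise ValueError(f"{name} must be a non-empty vector")
    rows = list(itertools.product(set_den, lengths_cap, ages_cap))
    out = pd.DataFrame(rows, columns=["set_den", "lengths_cap", "ages_cap"])
    out.insert(0, "survey", np.arange(1, len(out) + 1))
    return out


@dataclass(frozen=True)
class TestResults:
    """Design table plus pooled error tables and per-design error statistics."""

    surveys: pd.DataFrame
    total_strat_error: pd.DataFrame = field(repr=False)
    length_strat_error: pd.DataFrame = field(repr=False)
    age_strat_error: pd.DataFrame = field(repr=False)
    total_strat_error_stats: pd.DataFrame = field(repr=False)
    length_strat_error_stats: pd.DataFrame = field(repr=False)
    age_strat_error_stats: pd.DataFrame = field(repr=False)
    n_sims: int = 1
    n_loops: int = 1
    seed: int = 0


def _spec_for(base: SurveySpec, row: pd.Series, n_sims: int) -> SurveySpec:
    return replace(base, set_den=float(row["set_den"]),
                   lengths_cap=int(row["lengths_cap"]),
                   ages_cap=int(row["ages_cap"]), n_sims=n_sims)


def _run_task(spatial: SpatialPopulation, base: SurveySpec, opts: StratOptions,
              row: pd.Series, loop: int, n_sims: int, seed: int) -> dict:
    """One (design, loop) batch -> error tables tagged with the survey id."""
    design = int(row["survey"])
    spec = _spec_for(base, row, n_sims)
    sv = sim_survey(spatial, spec, seed=seed, first_sim=loop * n_sims, stream=design)
    est = run_strat(sv, opts)
    err = strat_error(est, sv)
    out = {}
    for kind in _KINDS:
        tab = getattr(err, f"{kind}_strat_error").copy()
        tab.insert(0, "survey", design)
        out[kind] = tab
    return out


def _task_paths(export_dir: Path, design: int, loop: int) -> dict:
    stem = f"design{design:03d}_loop{loop:03d}"
    return {k: export_dir / f"{stem}_{k}.csv" for k in _KINDS}


def _config_payload(surveys, n_sims, n_loops, seed, base, opts) -> dict:
    from dataclasses import asdict
    return {
        "surveys": surveys.to_dict(orient="list"),
        "n_sims": int(n_sims), "n_loops": int(n_loops), "seed": int(seed),
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(base).items()},
        "strat": {"length_group": opts.length_group, "alk_scale": opts.alk_scale},
    }


def _hash_config(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def _aggregate(surveys: pd.DataFrame, tables: dict, n_sims: int, n_loops: int,
               seed: int) -> TestResults:
    pooled = {}
    stats = {}
    for kind in _KINDS:
        tab = pd.concat(tables[kind], ignore_index=True)
        tab = tab.sort_values(["survey", "sim"] +
                              (["year"] if "year" in tab else [])).reset_index(drop=True)
        pooled[kind] = tab
        st = (tab.groupby("survey")["error"]
              .apply(lambda e: pd.Series(_error_metrics(e.to_numpy())))
              .unstack().reset_index())
        stats[kind] = st
    return TestResults(surveys=surveys.copy(),
                       total_strat_error=pooled["total"],
                       length_strat_error=pooled["length"],
                       age_strat_error=pooled["age"],
                       total_strat_error_stats=stats["total"],
                       length_strat_error_stats=stats["length"],
                       age_strat_error_stats=stats["age"],
                       n_sims=n_sims, n_loops=n_loops, seed=seed)


def _execute(spatial, surveys, base, opts, n_sims, n_loops, workers, export_dir,
             seed, todo) -> None:
    """Run the (design, loop) tasks in ``todo``, checkpointing if requested."""
    def finish(design, loop, result):
        if export_dir is not None:
            paths = _task_paths(export_dir, design, loop)
            for kind in _KINDS:
                result[kind].to_csv(paths[kind], index=False)

    rows = {int(r["survey"]): r for _, r in surveys.iterrows()}
    t0 = time.monotonic()
    if workers <= 1:
        for i, (design, loop) in enumerate(todo):
            result = _run_task(spatial, base, opts, rows[design], loop, n_sims, seed)
            finish(design, loop, result)
            done, total = i + 1, len(todo)
            eta = (time.monotonic() - t0) / done * (total - done)
            logger.info("design %d loop %d done (%d/%d, eta %.0fs)",
                        design, loop, done, total, eta)
    else:
        with ProcessPoolExecutor(max_workers=workers) as ex:
            futs = {(d, l): ex.submit(_run_task, spatial, base, opts, rows[d], l,
                                      n_sims, seed) for d, l in todo}
            for (design, loop), fut in futs.items():
                finish(design, loop, fut.result())


def _collect(export_dir, spatial, surveys, base, opts, n_sims, n_loops, seed,
             keep_tables: Optional[dict] = None) -> TestResults:
    tables = keep_tables if keep_tables is not None else {k: [] for k in _KINDS}
    if export_dir is not None:
        tables = {k: [] for k in _KINDS}
        for _, row in surveys.iterrows():
            for loop in range(n_loops):
                paths = _task_paths(export_dir, int(row["survey"]), loop)
                for kind in _KINDS:
                    tables[kind].append(pd.read_csv(paths[kind]))
    return _aggregate(surveys, tables, n_sims, n_loops, seed)


def test_surveys(spatial: SpatialPopulation, surveys: pd.DataFrame,
                 base_spec: SurveySpec | None = None,
                 strat_options: StratOptions | None = None,
                 n_sims: int = 1, n_loops: int = 1, workers: int = 1,
                 export_dir=None, seed: int = 0) -> TestResults:
    """Simulate, analyse and score every survey design over one population."""
    base = base_spec if base_spec is not None else SurveySpec()
    opts = strat_options if strat_options is not None else StratOptions()
    if workers < 1:
        raise ValueError("workers must be >= 1")
    if not {"survey", "set_den", "lengths_cap", "ages_cap"} <= set(surveys.columns):
        raise ValueError("surveys table needs survey/set_den/lengths_cap/ages_cap")

    export = Path(export_dir) if export_dir is not None else None
    if export is not None:
        export.mkdir(parents=True, exist_ok=True)
        payload = _config_payload(surveys, n_sims, n_loops, seed, base, opts)
        manifest = {"config": payload, "config_hash": _hash_config(payload)}
        (export / "manifest.json").write_text(json.dumps(manifest, indent=2))
        surveys.to_csv(export / "surveys.csv", index=False)
        save_spatial(spatial, export / "spatial")

    todo = [(int(r["survey"]), loop) for _, r in surveys.iterrows()
            for loop in range(n_loops)]
    if export is None:
        # in-memory run
        tables = {k: [] for k in _KINDS}
        rows = {int(r["survey"]): r for _, r in surveys.iterrows()}
        if workers <= 1:
            for design, loop in todo:
                res = _run_task(spatial, base, opts, rows[design], loop, n_sims, seed)
                for kind in _KINDS:
                    tables[kind].append(res[kind])
        else:
            with ProcessPoolExecutor(max_workers=workers) as ex:
                futs = [(d, l, ex.submit(_run_task, spatial, base, opts, rows[d], l,
                                         n_sims, seed)) for d, l in todo]
                for d, l, fut in futs:
                    res = fut.result()
                    for kind in _KINDS:
                        tables[kind].append(res[kind])
        return _aggregate(surveys, tables, n_sims, n_loops, seed)

    _execute(spatial, surveys, base, opts, n_sims, n_loops, workers, export, seed, todo)
    return _collect(export, spatial, surveys, base, opts, n_sims, n_loops, seed)


def resume_test(export_dir, workers: int = 1) -> TestResults:
    """Finish (or just re-aggregate) a checkpointed ``test_surveys`` run."""
    export = Path(export_dir)
    man_path = export / "manifest.json"
    if not man_path.exists():
        raise ValueError(f"no manifest.json in {export}; not a test_surveys export")
    manifest = json.loads(man_path.read_text())
    payload = manifest.get("config")
    if payload is None or _hash_config(payload) != manifest.get("config_hash"):
        raise ValueError("manifest config hash mismatch; refusing to resume")

    surveys = pd.DataFrame(payload["surveys"])
    n_sims, n_loops, seed = payload["n_sims"], payload["n_loops"], payload["seed"]
    spec_kw = dict(payload["spec"])
    for key in ("trawl_dim", "q_table"):
        if spec_kw.get(key) is not None:
            spec_kw[key] = tuple(spec_kw[key])
    base = SurveySpec(**spec_kw)
    opts = StratOptions(**payload["strat"])
    spatial = load_spatial(export / "spatial")

    todo = [(int(r["survey"]), loop) for _, r in surveys.iterrows()
            for loop in range(n_loops)
            if not all(p.exists() for p in
                       _task_paths(export, int(r["survey"]), loop).values())]
    if todo:
        logger.info("resuming %d remaining (design, loop) tasks", len(todo))
        _execute(spatial, surveys, base, opts, n_sims, n_loops, workers, export,
                 seed, todo)
    return _collect(export, spatial, surveys, base, opts, n_sims, n_loops, seed)
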