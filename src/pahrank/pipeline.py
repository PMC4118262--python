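"""Pipeline orchestration: simulate -> classify -> aggregate -> fit -> rank
-> select -> report over the documented file contracts.

Each stage is also independently invocable from the CLI; the pipeline is a
pure function of (inputs, config, seed), so identical reruns produce
identical outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import classify, exposure, io, nbglmm, ranking, simulate
from .cohort import apply_filter
from .errors import ConfigError, PahrankError

logger = logging.getLogger("pahrank")


def _setup_run_log(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    if logger.level == logging.NOTSET or logger.level > logging.INFO:
        logger.setLevel(logging.INFO)
    return handler


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Run every stage; returns a dict of result objects and artifact paths.

    ``config`` is a validated config dict (see :func:`pahrank.io.load_config`
    / :func:`pahrank.io.validate_config`). Artifacts written to ``out_dir``
    (default ``config['paths']['out_dir']``): aggregates.csv, model.json,
    ranks.tsv, selection.tsv, comparison.json and run.log.
    """
    out_dir = Path(out_dir or config["paths"].get("out_dir") or ".")
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_log(out_dir)
    try:
        return _run(config, out_dir)
    except PahrankError:
        raise
    finally:
        handler.close()
        logger.removeHandler(handler)


def _run(config: dict, out_dir: Path) -> dict:
    paths = config["paths"]

    # --- simulate or read -------------------------------------------------
    if config.get("simulate"):
        scenario = simulate.get_preset(config["simulate"]["preset"], seed=config["seed"])
        facilities, residents, events = simulate.simulate_cohort(scenario)
        io.write_facilities(facilities, out_dir / "facilities.csv")
        io.write_residents(residents, out_dir / "residents.csv")
        io.write_events(events, out_dir / "events.csv")
        window = config["window"] or scenario.window
    else:
        for key in ("facilities", "residents", "events"):
            if not paths.get(key):
                raise ConfigError(f"paths.{key} required when not simulating")
        facilities, residents, events = io.read_cohort(
            paths["facilities"], paths["residents"], paths["events"]
        )
        if config["window"] is None:
            raise ConfigError("window required when reading an existing cohort")
        window = config["window"]

    # --- filter -----------------------------------------------------------
    facilities, residents = apply_filter(facilities, residents, config["filter"])
    res_ids = {r.resident_id for r in residents}
    events = [e for e in events if e.resident_id in res_ids]

    # --- classify ---------------------------------------------------------
    if paths.get("code_list"):
        code_list = classify.load_code_list(
            paths["code_list"], config["classification"]["max_position"]
        )
    else:
        code_list = classify.default_code_list(config["classification"]["max_position"])
    pah_counts = classify.count_pah_events(
        events, residents, code_list, window,
        acute_only=config["classification"]["acute_only"],
    )

    # --- aggregate --------------------------------------------------------
    aggs = exposure.aggregate_cohort(
        facilities, residents, pah_counts, window, mode=config["exposure"]["mode"]
    )
    nbglmm.aggregates_frame(aggs).to_csv(out_dir / "aggregates.csv", index=False)

    # --- fit --------------------------------------------------------------
    mcfg = config["model"]
    spec = nbglmm.NBMMSpec(
        covariates=tuple(mcfg["covariates"]),
        offset_mode=mcfg["offset_mode"],
        quadrature_points=mcfg["quadrature_points"],
    )
    if mcfg["unit"] == "resident":
        data = nbglmm.resident_frame(residents, pah_counts, window)
        data = data[data["person_years"] > 0].reset_index(drop=True)
    else:
        data = nbglmm.aggregates_frame(aggs)
        data = data[~data["flagged"]].reset_index(drop=True)
    if mcfg["backward"]:
        model, trace = nbglmm.backward_eliminate(spec, data, alpha=mcfg["alpha"])
    else:
        model = nbglmm.fit(spec, data)
        trace = []
    with open(out_dir / "model.json", "w") as fh:
        json.dump(model.summary_dict(), fh, indent=2)

    # --- rank -------------------------------------------------------------
    rcfg = config["ranking"]
    table = ranking.build_rank_table(
        aggs, model,
        per_bed=rcfg["per_bed"],
        residual_kind=rcfg["residual"],
        method4_absolute=rcfg["method4_absolute"],
    )
    io.write_rank_report(table, out_dir / "ranks.tsv", sort_by=rcfg["sort_by"])

    # --- select + report --------------------------------------------------
    scfg = config["selection"]
    selection = ranking.select_top(
        table, scfg["method"], scfg["top_n"], stratified=scfg["stratified"]
    )
    selection.to_csv(out_dir / "selection.tsv", sep="\t", index=False,
                     float_format="%.10g")

    comparisons = {}
    for a, b in (("method1", "method2"), ("method2", "method3"),
                 ("method3", "method4")):
        if f"rank_{b}" in table.frame.columns:
            c = ranking.compare_methods(table, a, b, top_n=scfg["top_n"])
            c.pop("rank_shifts")
            comparisons[f"{a}_vs_{b}"] = c
    with open(out_dir / "comparison.json", "w") as fh:
        json.dump(comparisons, fh, indent=2)

    logger.info("stage=done out_dir=%s facilities_ranked=%d", out_dir, len(aggs))
    return {
        "facilities": facilities,
        "residents": residents,
        "events": events,
        "pah_counts": pah_counts,
        "aggregates": aggs,
        "model": model,
        "elimination_trace": trace,
        "rank_table": table,
        "selection": selection,
        "comparisons": comparisons,
        "window": window,
        "out_dir": out_dir,
    }


__all__ = ["run_pipeline"]
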