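"""End-to-end pipeline: generate (or load) -> condition -> quantify.

Stages run in the canonical order

    simulate/load -> normalize_growth -> detrend -> smooth -> rescale01
                  -> metrics

and every artifact (tidy traces CSV, report JSON, 0-1 heatmap matrix CSV,
run log with seed and parameter hash) is written under the output
directory.  Identical config and seed produce byte-identical reports.
"""

from __future__ import annotations

import json
import os
from typing import Optional

import pandas as pd

from .config import PipelineConfig
from .metrics import MetricsReport, compute_metrics
from .preprocess import preprocess_matrix
from .simulate import simulate_consortium, simulate_ensemble
from .traces import read_traces, write_traces

__all__ = ["PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    pass


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineError(f"stage '{name}' failed: {exc}") from exc


def run_pipeline(config: PipelineConfig, outdir: Optional[str] = None) -> MetricsReport:
    """Run the full analysis; returns the MetricsReport and writes artifacts."""
    outdir = outdir or config.outdir
    toxin_field = None
    if config.traces_path is not None:
        traceset = _stage("load", read_traces, config.traces_path)
    elif config.toxin is not None:
        traceset, toxin_field = _stage(
            "simulate",
            simulate_consortium,
            config.program,
            config.circuit,
            config.circuit,
            config.switch,
            config.toxin,
            config.n_communities,
            config.seed,
        )
    else:
        traceset = _stage(
            "simulate",
            simulate_ensemble,
            config.n_communities,
            config.program,
            config.circuit,
            config.switch,
            config.seed,
        )
    processed = _stage("preprocess", preprocess_matrix, traceset.degfp, traceset.mcherry)
    report = _stage(
        "metrics",
        compute_metrics,
        processed,
        traceset.time_min,
        config.program,
        nups=config.nups,
        ndowns=config.ndowns,
        min_prominence=config.min_prominence,
        cycle_coverage=config.cycle_coverage,
    )
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        write_traces(traceset, os.path.join(outdir, "traces.csv"))
        with open(os.path.join(outdir, "report.json"), "w", encoding="utf-8") as fh:
            json.dump(report.to_dict(), fh, sort_keys=True, indent=2)
            fh.write("\n")
        heat = pd.DataFrame(
            processed.T,
            index=traceset.community_ids,
            columns=[f"{t:.1f}" for t in traceset.time_min],
        )
        heat.to_csv(os.path.join(outdir, "heatmap.csv"))
        if toxin_field is not None:
            pd.DataFrame(
                {"time_min": traceset.time_min, "toxin": toxin_field}
            ).to_csv(os.path.join(outdir, "toxin.csv"), index=False)
        log = {
            "resolved_config": config.to_dict(),
            "seed": config.seed,
            "params_hash": traceset.meta.get("params_hash"),
            "n_communities": traceset.n_communities,
        }
        with open(os.path.join(outdir, "run_log.json"), "w", encoding="utf-8") as fh:
            json.dump(log, fh, sort_keys=True, indent=2)
            fh.write("\n")
    return report
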