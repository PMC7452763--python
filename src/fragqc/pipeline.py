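"""End-to-end orchestration: simulate/read -> merge -> quantify -> ANOVA.

Every run writes a manifest (config, seed, library versions, config hash)
and stamps each CSV output with the config hash, so a run is reproducible
from its own outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from . import __version__
from .core import TREATMENT_FACTORS
from .hmw import (
    HMW_THRESHOLD_BP,
    RNA_EXCLUSION_BP,
    hmw_report,
    reports_to_frame,
    scale_factors,
)
from .io import read_design, read_runs, write_design, write_traces
from .merge import align_runs, merge_sample, summaries_to_frame, summarize_group
from .quality import (
    GQN_THRESHOLD_BP,
    compare_models,
    factorial_anova,
    score_samples,
)
from .simulate import SimulationConfig, simulate_experiment

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Serializable settings for one pipeline run."""

    simulation: SimulationConfig | None = None
    trace_paths: tuple[str, ...] = ()
    design_path: str | None = None
    outdir: str = "fragqc-out"
    clip_first: bool = False
    ci_method: str = "t"
    hmw_threshold: float = HMW_THRESHOLD_BP
    min_size: float = RNA_EXCLUSION_BP
    gqn_threshold: float = GQN_THRESHOLD_BP
    seed: int | None = None  # overrides simulation.seed when given
    make_plots: bool = False  # cosmetic; the plot DATA is always written

    def __post_init__(self) -> None:
        if self.simulation is None and not (self.trace_paths and self.design_path):
            raise ValueError(
                "either simulation settings or trace/design paths are required"
            )
        if self.ci_method not in ("t", "normal"):
            raise ValueError("ci_method must be 't' or 'normal'")
        if self.min_size <= 0 or self.hmw_threshold <= self.min_size:
            raise ValueError("need 0 < min_size < hmw_threshold")
        if self.gqn_threshold < self.min_size:
            raise ValueError("gqn_threshold must be >= min_size")

    def to_dict(self) -> dict:
        return {
            "simulation": self.simulation.to_dict() if self.simulation else None,
            "trace_paths": list(self.trace_paths),
            "design_path": self.design_path,
            "outdir": self.outdir,
            "clip_first": self.clip_first,
            "ci_method": self.ci_method,
            "hmw_threshold": self.hmw_threshold,
            "min_size": self.min_size,
            "gqn_threshold": self.gqn_threshold,
            "seed": self.seed,
            "make_plots": self.make_plots,
        }

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    outdir: str
    manifest: dict
    cell_reports: list
    solution_reports: list
    scale_table: "pd.DataFrame"
    anova_full: object
    anova_solution: object
    comparison: object
    files: dict[str, str] = field(default_factory=dict)


def _write_csv(frame: pd.DataFrame, path: str, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        frame.to_csv(fh, index=False)


def _stage(name: str):
    logger.info("pipeline stage: %s", name)


def _render_panels(summaries, path: str, hmw_threshold: float) -> None:
    """One panel per treatment group; lines per time point, shaded CI."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups: dict[tuple, list] = {}
    for s in summaries:
        groups.setdefault(tuple(s.group_key.items()), []).append(s)
    n = len(groups)
    ncols = min(n, 4)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows),
                             squeeze=False, sharey=True)
    for ax, (key, members) in zip(axes.flat, sorted(groups.items())):
        for s in sorted(members, key=lambda m: m.time_days):
            ax.plot(s.sizes, s.mean_rfu, lw=1, label=f"{s.time_days} d")
            ax.fill_between(s.sizes, s.ci_low, s.ci_high, alpha=0.2)
        ax.axvline(hmw_threshold, ls=":", color="k", lw=0.8)
        ax.set_xscale("log")
        ax.set_title(", ".join(f"{k}={v}" for k, v in key), fontsize=8)
        ax.set_xlabel("size (bp)")
    axes.flat[0].set_ylabel("RFU")
    axes.flat[0].legend(fontsize=7)
    for ax in axes.flat[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis chain and write the report bundle.

    Outputs under ``config.outdir``: simulated inputs (when simulating),
    per-cell and per-solution group summaries (the data behind the
    treatment-panel and solution-panel figures), the HMW report, the
    DESS/ETOH scale-factor table, per-sample fragmentation scores, the
    full-factorial and solution-only ANOVA tables, the nested-model
    comparison, and a run manifest.
    """
    os.makedirs(config.outdir, exist_ok=True)
    chash = config.hash()
    files: dict[str, str] = {}

    def out(name: str) -> str:
        path = os.path.join(config.outdir, name)
        files[name] = path
        return path

    _stage("inputs")
    if config.simulation is not None:
        sim_config = config.simulation
        if config.seed is not None:
            sim_config = dataclasses.replace(sim_config, seed=config.seed)
        dataset = simulate_experiment(sim_config)
        traces = dataset.traces
        design = dataset.design
        for run_id, run_traces in dataset.runs.items():
            write_traces(run_traces, out(f"traces_{run_id}.csv"),
                         header_lines=[f"config_hash={chash}"])
        write_design(design, out("design.csv"),
                     header_lines=[f"config_hash={chash}"])
        _write_csv(dataset.truth, out("truth.csv"), chash)
    else:
        traces = read_runs(config.trace_paths)
        design = read_design(config.design_path)
    recon = design.reconcile([t.sample_id for t in traces])
    if recon["traces_only"]:
        raise RuntimeError(
            f"stage inputs: traces without design rows: {recon['traces_only'][:5]}"
        )

    _stage("merge")
    merged = [merge_sample(t, clip_first=config.clip_first) for t in traces]
    aligned = align_runs(merged)

    _stage("summarize")
    cell_summaries = summarize_group(
        aligned, design.rows, group_by=TREATMENT_FACTORS, ci_method=config.ci_method
    )
    solution_summaries = summarize_group(
        aligned, design.rows, group_by=("solution",), ci_method=config.ci_method
    )
    _write_csv(summaries_to_frame(cell_summaries),
               out("summary_by_cell.csv"), chash)
    _write_csv(summaries_to_frame(solution_summaries),
               out("summary_by_solution.csv"), chash)

    _stage("quantify")
    cell_reports = hmw_report(cell_summaries, config.hmw_threshold, config.min_size)
    solution_reports = hmw_report(
        solution_summaries, config.hmw_threshold, config.min_size
    )
    scale_table = scale_factors(solution_reports)
    _write_csv(reports_to_frame(cell_reports), out("hmw_by_cell.csv"), chash)
    _write_csv(reports_to_frame(solution_reports), out("hmw_by_solution.csv"), chash)
    _write_csv(scale_table.rounded(), out("scale_factors.csv"), chash)

    _stage("anova")
    scores = score_samples(merged, config.gqn_threshold, config.min_size)
    _write_csv(scores, out("gqn_scores.csv"), chash)
    design_frame = design.to_frame()
    anova_full = factorial_anova(scores, design_frame, terms="full")
    anova_solution = factorial_anova(scores, design_frame, terms="solution")
    comparison = compare_models(anova_full, anova_solution)
    _write_csv(anova_full.to_frame(), out("anova_full.csv"), chash)
    _write_csv(anova_solution.to_frame(), out("anova_solution.csv"), chash)

    if config.make_plots:
        _stage("plots")
        _render_panels(solution_summaries, out("panels_by_solution.png"),
                       config.hmw_threshold)
        _render_panels(cell_summaries, out("panels_by_cell.png"),
                       config.hmw_threshold)

    _stage("report")
    manifest = {
        "config": config.to_dict(),
        "config_hash": chash,
        "seed": (config.seed if config.seed is not None
                 else (config.simulation.seed if config.simulation else None)),
        "n_samples": len(traces),
        "n_cells": int(design.n_cells),
        "n_solution_groups": len({r.group_key["solution"] for r in solution_reports}),
        "balanced_design": bool(design.balanced),
        "model_comparison": {
            "f_stat": comparison.f_stat,
            "df_num": comparison.df_num,
            "df_den": comparison.df_den,
            "p_value": comparison.p_value,
        },
        "versions": {
            "fragqc": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(
        outdir=config.outdir,
        manifest=manifest,
        cell_reports=cell_reports,
        solution_reports=solution_reports,
        scale_table=scale_table.table,
        anova_full=anova_full,
        anova_solution=anova_solution,
        comparison=comparison,
        files=files,
    )
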