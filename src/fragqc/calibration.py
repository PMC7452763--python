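"""Simulation-based calibration of the factorial ANOVA.

Two repeated-simulation diagnostics: the type-I error of the solution term
when the generator applies no treatment effects, and how often the
solution term dominates the ANOVA table under the default (strong
solution effect) study conditions.  Both run the same per-sample scoring
path as the pipeline (merge -> fragmentation score -> factorial fit).
"""

from __future__ import annotations

import numpy as np

from .merge import merge_sample
from .quality import factorial_anova, score_samples
from .simulate import SimulationConfig, simulate_experiment

#: Grid used for the repeated simulations: coarser than the default so the
#: hundreds of replicates stay cheap, while still resolving all three
#: size components.
CALIBRATION_GRID = np.geomspace(75.0, 60_000.0, 160)


def _rep_anova(config: SimulationConfig):
    dataset = simulate_experiment(config)
    merged = [merge_sample(t) for t in dataset.traces]
    scores = score_samples(merged)
    return factorial_anova(scores, dataset.design.to_frame(), terms="full",
                           check_balanced=False)


def null_solution_rejection_rate(base_seed: int, n_reps: int = 500,
                                 alpha: float = 0.05) -> float:
    """Rejection rate of the solution term with all multipliers at 1.

    Under this null the solution factor has no effect on decay, so the
    rate should sit near ``alpha``.
    """
    rejections = 0
    for rep in range(n_reps):
        config = SimulationConfig(
            size_grid=CALIBRATION_GRID, solution_multiplier=1.0,
            temp_multiplier=1.0, heat_multiplier=1.0,
            seed=(base_seed + rep) % 2**31,
        )
        if _rep_anova(config).p_value("solution") < alpha:
            rejections += 1
    return rejections / n_reps


def solution_smallest_p_rate(base_seed: int, n_reps: int = 200) -> float:
    """Fraction of replicates where solution is the smallest-p term under
    the default strong solution effect."""
    hits = 0
    for rep in range(n_reps):
        config = SimulationConfig(size_grid=CALIBRATION_GRID,
                                  seed=(base_seed + rep) % 2**31)
        table = _rep_anova(config).table.set_index("term")["p_value"]
        if table.idxmin() == "solution":
            hits += 1
    return hits / n_reps
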