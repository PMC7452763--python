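"""Synthetic electropherogram generator for the storage experiment.

The generator emulates the degradation phenomenology of preserved fin-clip
DNA as seen on a capillary-electrophoresis trace: a low-molecular-weight
(LMW) component below 250 bp (RNA carry-over and very short fragments), a
degraded smear centred near 1 kbp, and a high-molecular-weight (HMW)
component centred near 40 kbp.  Each component is a log-normal density on
the size axis; a sample's noise-free signal is

    rfu(s) = A_fish * amplitude * sum_k w_k(t) * lognorm_k(s)

where the HMW weight decays exponentially with storage time,
``w_H(t) = w_H(0) * exp(-r t)``, and the lost mass moves to the degraded
~1 kbp component (fragmentation shortens molecules; it does not destroy
them).  The per-day rate r is the base rate times treatment multipliers:

    r = decay_base_rate * (solution_multiplier if ETOH)
                        * (temp_multiplier if room temperature)
                        * (heat_multiplier if not heat-treated)

so the reference cell (DESS, cold, heat-treated) decays at the base rate.
Per-fish amplitude effects are log-normal and shared by all of a fish's
samples; each simulated run perturbs the size axis multiplicatively
(instrument calibration drift between runs); detector noise is additive
Gaussian per grid point and may push RFU below zero, which the merge stage
clips.

The default configuration mirrors the 200-sample factorial design: 5 fish
x 2 solutions x 2 heat treatments x 2 temperatures x 5 storage times, with
one simulated instrument run per time point.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    DEFAULT_TIME_POINTS,
    HEAT_LEVELS,
    SOLUTION_LEVELS,
    TEMPERATURE_LEVELS,
    Electropherogram,
    SampleDesign,
)
from .io import DesignTable, validate_design

COMPONENT_NAMES = ("lmw", "degraded", "hmw")


@dataclass(frozen=True)
class ComponentParams:
    """Log-normal shape of one size component: location and spread of ln(size)."""

    log_mean: float
    log_sd: float

    def pdf(self, sizes: np.ndarray) -> np.ndarray:
        return stats.lognorm.pdf(sizes, s=self.log_sd, scale=np.exp(self.log_mean))

    def cdf(self, sizes) -> np.ndarray:
        return stats.lognorm.cdf(sizes, s=self.log_sd, scale=np.exp(self.log_mean))


def _default_components() -> dict[str, ComponentParams]:
    return {
        "lmw": ComponentParams(np.log(150.0), 0.35),
        "degraded": ComponentParams(np.log(1_000.0), 0.55),
        "hmw": ComponentParams(np.log(40_000.0), 0.22),
    }


def _default_grid() -> np.ndarray:
    return np.geomspace(75.0, 60_000.0, 500)


@dataclass
class SimulationConfig:
    """Study conditions for the simulated storage experiment.

    Defaults reproduce the 200-sample design; rate multipliers are the
    treatment effects (values > 1 accelerate HMW decay for ETOH, room
    temperature, and untreated samples respectively).  ``amplitude`` is the
    total noise-free signal mass of one trace in RFU*bp.
    """

    n_fish: int = 5
    replicates_per_cell: int = 5
    time_points_days: tuple[int, ...] = DEFAULT_TIME_POINTS
    size_grid: np.ndarray = field(default_factory=_default_grid)
    components: dict[str, ComponentParams] = field(default_factory=_default_components)
    initial_weights: tuple[float, float, float] = (0.2, 0.3, 0.5)  # lmw, degraded, hmw
    decay_base_rate: float = 0.005       # per day, reference cell
    solution_multiplier: float = 20.0    # ETOH vs DESS
    temp_multiplier: float = 2.0         # room vs cold
    heat_multiplier: float = 1.5         # untreated vs heat-treated
    fish_effect_sd: float = 0.15         # log-scale SD of per-fish amplitude
    noise_sd: float = 1.0                # RFU, additive per grid point
    size_jitter_frac: float = 0.005      # per-run multiplicative size perturbation
    amplitude: float = 2.0e5             # RFU*bp total mass per trace
    run_scheme: str = "per-time"         # or "single"
    seed: int = 0

    def __post_init__(self) -> None:
        self.size_grid = np.asarray(self.size_grid, dtype=float)
        w = np.asarray(self.initial_weights, dtype=float)
        if len(w) != 3 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("initial_weights must be 3 nonnegative values summing to 1")
        if set(self.components) != set(COMPONENT_NAMES):
            raise ValueError(f"components must be keyed {COMPONENT_NAMES}")
        for m in (self.solution_multiplier, self.temp_multiplier, self.heat_multiplier):
            if m <= 0:
                raise ValueError("rate multipliers must be > 0")
        if self.decay_base_rate < 0:
            raise ValueError("decay_base_rate must be >= 0")
        g = self.size_grid
        if len(g) < 2 or np.any(np.diff(g) <= 0):
            raise ValueError("size_grid must be strictly increasing")
        if not (g.min() < 250 and g.max() > 20_000):
            raise ValueError("size_grid must span the 250 bp and 20 kbp boundaries")
        if self.run_scheme not in ("per-time", "single"):
            raise ValueError("run_scheme must be 'per-time' or 'single'")
        if self.noise_sd < 0 or self.size_jitter_frac < 0 or self.fish_effect_sd < 0:
            raise ValueError("noise/jitter/fish-effect scales must be >= 0")

    @classmethod
    def from_dict(cls, mapping: dict) -> "SimulationConfig":
        kwargs = dict(mapping)
        if "components" in kwargs:
            kwargs["components"] = {
                k: ComponentParams(**v) if isinstance(v, dict) else v
                for k, v in kwargs["components"].items()
            }
        for key in ("time_points_days", "initial_weights"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "n_fish": self.n_fish,
            "replicates_per_cell": self.replicates_per_cell,
            "time_points_days": list(self.time_points_days),
            "size_grid": {
                "min": float(self.size_grid.min()),
                "max": float(self.size_grid.max()),
                "n": int(len(self.size_grid)),
            },
            "components": {
                k: {"log_mean": v.log_mean, "log_sd": v.log_sd}
                for k, v in self.components.items()
            },
            "initial_weights": list(self.initial_weights),
            "decay_base_rate": self.decay_base_rate,
            "solution_multiplier": self.solution_multiplier,
            "temp_multiplier": self.temp_multiplier,
            "heat_multiplier": self.heat_multiplier,
            "fish_effect_sd": self.fish_effect_sd,
            "noise_sd": self.noise_sd,
            "size_jitter_frac": self.size_jitter_frac,
            "amplitude": self.amplitude,
            "run_scheme": self.run_scheme,
            "seed": self.seed,
        }


def _child_rng(seed: int, *keys) -> np.random.Generator:
    digest = hashlib.sha256(("/".join(map(str, keys))).encode()).digest()
    stream = int.from_bytes(digest[:4], "little")
    return np.random.default_rng([int(seed), stream])


def decay_rate(config: SimulationConfig, design: SampleDesign) -> float:
    """Per-day HMW loss rate for one sample's treatment cell."""
    r = config.decay_base_rate
    if design.solution == "ETOH":
        r *= config.solution_multiplier
    if design.temperature == "room":
        r *= config.temp_multiplier
    if design.heat == "untreated":
        r *= config.heat_multiplier
    return r


def component_weights(
    config: SimulationConfig, design: SampleDesign
) -> tuple[float, float, float]:
    """Mixture weights (lmw, degraded, hmw) at the sample's storage time.

    Mass conservation holds exactly: HMW mass lost to decay reappears in
    the degraded component, so the weights sum to 1 at every time.
    """
    w_l, w_d, w_h0 = config.initial_weights
    w_h = w_h0 * np.exp(-decay_rate(config, design) * design.time_days)
    return (w_l, w_d + (w_h0 - w_h), w_h)


def fish_amplitude(config: SimulationConfig, fish: str) -> float:
    """Per-fish log-normal amplitude multiplier, stable across samples."""
    if config.fish_effect_sd == 0:
        return 1.0
    rng = _child_rng(config.seed, "fish", fish)
    return float(np.exp(config.fish_effect_sd * rng.standard_normal()))


def run_jitter(config: SimulationConfig, run_id: str) -> float:
    """Multiplicative size-axis perturbation shared by all traces of a run."""
    if config.size_jitter_frac == 0:
        return 0.0
    rng = _child_rng(config.seed, "run", run_id)
    return float(config.size_jitter_frac * rng.standard_normal())


def _component_pdfs(config: SimulationConfig) -> np.ndarray:
    """Component densities on the grid; fixed per config, so cacheable."""
    return np.vstack(
        [config.components[name].pdf(config.size_grid) for name in COMPONENT_NAMES]
    )


def simulate_trace(
    config: SimulationConfig,
    design: SampleDesign,
    rng: np.random.Generator | None = None,
    component_pdfs: np.ndarray | None = None,
) -> Electropherogram:
    """Simulate one sample's electropherogram.

    The reported size axis is the configured grid scaled by the run's
    jitter (a calibration drift: true size s is read out as s*(1+jitter));
    the noise-free RFU values are the mixture density at the true sizes.
    ``rng`` drives the additive detector noise only; when omitted it is
    derived deterministically from the seed and sample ID, so the same
    seed, config and design always give a bit-identical trace.
    ``component_pdfs`` lets a caller reuse the grid densities across the
    many traces of one experiment.
    """
    if rng is None:
        rng = _child_rng(config.seed, "noise", design.sample_id)
    weights = np.asarray(component_weights(config, design))
    if component_pdfs is None:
        component_pdfs = _component_pdfs(config)
    signal = weights @ component_pdfs
    signal *= config.amplitude * fish_amplitude(config, design.fish)
    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, size=len(signal))
    sizes = config.size_grid * (1.0 + run_jitter(config, design.run_id))
    return Electropherogram(design.sample_id, design.run_id, sizes, signal)


def hmw_window_fraction(config: SimulationConfig, design: SampleDesign,
                        hmw_threshold: float = 20_000.0,
                        min_size: float = 250.0) -> float:
    """Analytic HMW fraction of the signal inside the analysis window.

    This is what the AUC pipeline estimates: mixture mass at or above the
    HMW threshold divided by mixture mass at or above ``min_size``, both
    restricted to the simulated size range (the instrument observes
    nothing outside its grid).
    """
    lo = max(min_size, float(config.size_grid.min()))
    hi = float(config.size_grid.max())
    weights = component_weights(config, design)
    num = den = 0.0
    for w, name in zip(weights, COMPONENT_NAMES):
        comp = config.components[name]
        den += w * float(comp.cdf(hi) - comp.cdf(lo))
        num += w * float(comp.cdf(hi) - comp.cdf(max(hmw_threshold, lo)))
    return num / den if den > 0 else float("nan")


@dataclass
class SimulatedDataset:
    """Traces, design and ground truth of one simulated experiment."""

    traces: list[Electropherogram]
    design: DesignTable
    truth: pd.DataFrame  # per-sample weights, decay rate, HMW fractions
    config: SimulationConfig

    @property
    def runs(self) -> dict[str, list[Electropherogram]]:
        grouped: dict[str, list[Electropherogram]] = {}
        for t in self.traces:
            grouped.setdefault(t.run_id, []).append(t)
        return grouped


def _run_id(config: SimulationConfig, time_days: int) -> str:
    if config.run_scheme == "single":
        return "run-all"
    return f"run-{time_days:03d}d"


def simulate_experiment(config: SimulationConfig) -> SimulatedDataset:
    """Simulate the full factorial storage experiment.

    Emits n_fish-replicated traces for every cell of the solution x heat x
    temperature x time crossing (200 at defaults), with replicate identity
    tied to fish as in the real design, one simulated instrument run per
    time point (or a single run), and per-sample ground truth.
    """
    designs: list[SampleDesign] = []
    truth_rows = []
    traces = []
    pdfs = _component_pdfs(config)
    for t in config.time_points_days:
        run = _run_id(config, t)
        for solution in SOLUTION_LEVELS:
            for heat in HEAT_LEVELS:
                for temperature in TEMPERATURE_LEVELS:
                    for rep in range(config.replicates_per_cell):
                        fish = f"fish{(rep % config.n_fish) + 1}"
                        sid = f"{fish}_{solution}_{heat}_{temperature}_{t}d"
                        if config.replicates_per_cell > config.n_fish:
                            sid += f"_r{rep + 1}"
                        design = SampleDesign(
                            sample_id=sid, fish=fish, solution=solution,
                            heat=heat, temperature=temperature,
                            time_days=int(t), run_id=run,
                        )
                        designs.append(design)
                        traces.append(
                            simulate_trace(config, design, component_pdfs=pdfs)
                        )
                        w_l, w_d, w_h = component_weights(config, design)
                        truth_rows.append(
                            {
                                "sample_id": sid,
                                "w_lmw": w_l,
                                "w_degraded": w_d,
                                "w_hmw": w_h,
                                "decay_rate": decay_rate(config, design),
                                "hmw_frac_window": hmw_window_fraction(config, design),
                            }
                        )
    table = validate_design(designs)
    return SimulatedDataset(
        traces=traces,
        design=table,
        truth=pd.DataFrame(truth_rows),
        config=config,
    )
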