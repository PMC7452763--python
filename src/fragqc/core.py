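"""Domain containers shared across the pipeline.

An :class:`Electropherogram` is one sample's fluorescence trace (RFU versus
fragment size in bp) from a capillary-electrophoresis instrument run.  A
:class:`SampleDesign` records the preservation-experiment factor levels for
one sample: which fish the fin clip came from, the storage solution (DESS or
ethanol), whether the sample was heat-treated, the storage temperature, and
the storage time in days before extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SOLUTION_LEVELS = ("DESS", "ETOH")
HEAT_LEVELS = ("treated", "untreated")
TEMPERATURE_LEVELS = ("cold", "room")
DEFAULT_TIME_POINTS = (1, 7, 14, 30, 90)

#: Factor columns required in a design table, beside sample_id and run_id.
FACTOR_COLUMNS = ("fish", "solution", "heat", "temperature", "time_days")

#: The treatment factors that may be used for grouping (time is always
#: a grouping variable on top of these).
TREATMENT_FACTORS = ("solution", "heat", "temperature")

_LEVELS = {
    "solution": SOLUTION_LEVELS,
    "heat": HEAT_LEVELS,
    "temperature": TEMPERATURE_LEVELS,
}


class DesignError(ValueError):
    """A sample's metadata violates the experimental-design schema."""


@dataclass
class Electropherogram:
    """One sample's (size bp, RFU) trace, tagged with sample and run IDs.

    Negative RFU values are legal on input: instrument baseline subtraction
    can push the signal slightly below zero.  Clipping happens at the merge
    stage, not here.
    """

    sample_id: str
    run_id: str
    sizes: np.ndarray
    rfu: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.rfu = np.asarray(self.rfu, dtype=float)
        if self.sizes.ndim != 1 or self.rfu.ndim != 1:
            raise ValueError("sizes and rfu must be one-dimensional")
        if len(self.sizes) != len(self.rfu):
            raise ValueError(
                f"sample {self.sample_id!r}: sizes ({len(self.sizes)}) and "
                f"rfu ({len(self.rfu)}) differ in length"
            )
        if len(self.sizes) < 2:
            raise ValueError(f"sample {self.sample_id!r}: need at least 2 points")
        if np.any(self.sizes <= 0):
            raise ValueError(f"sample {self.sample_id!r}: fragment sizes must be > 0")
        if np.any(np.diff(self.sizes) <= 0):
            bad = int(np.flatnonzero(np.diff(self.sizes) <= 0)[0]) + 1
            raise ValueError(
                f"sample {self.sample_id!r}: size axis not strictly increasing "
                f"at row {bad} (size {self.sizes[bad]:g})"
            )

    def __len__(self) -> int:
        return len(self.sizes)


@dataclass(frozen=True)
class SampleDesign:
    """Factor levels of the storage experiment for one sample."""

    sample_id: str
    fish: str
    solution: str
    heat: str
    temperature: str
    time_days: int
    run_id: str = ""

    def __post_init__(self) -> None:
        for name in ("solution", "heat", "temperature"):
            value = getattr(self, name)
            allowed = _LEVELS[name]
            if value not in allowed:
                raise DesignError(
                    f"sample {self.sample_id!r}: unknown {name} level {value!r}; "
                    f"allowed: {', '.join(allowed)}"
                )
        t = self.time_days
        if not (isinstance(t, (int, np.integer)) and not isinstance(t, bool)) or t <= 0:
            raise DesignError(
                f"sample {self.sample_id!r}: time_days must be a positive "
                f"integer, got {t!r}"
            )

    @property
    def cell(self) -> tuple:
        """The treatment cell: (solution, heat, temperature, time_days)."""
        return (self.solution, self.heat, self.temperature, self.time_days)
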