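"""CSV input/output for electropherogram exports and design metadata.

Trace files follow the common PROsize-style export convention: a wide CSV
with a "Size (bp)" column followed by one RFU column per sample, one file
per instrument run.  The design table is a tidy CSV with one row per sample
carrying the factor levels of the storage experiment.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import FACTOR_COLUMNS, Electropherogram, SampleDesign

logger = logging.getLogger(__name__)

SIZE_COLUMN = "Size (bp)"

_DESIGN_COLUMNS = ("sample_id",) + FACTOR_COLUMNS + ("run_id",)


def read_traces(
    path: str,
    size_column: str = SIZE_COLUMN,
    run_id: str | None = None,
) -> list[Electropherogram]:
    """Read one run's electropherogram export.

    The first column (or ``size_column``) is the size axis in bp; every
    remaining column is one sample's RFU trace.  ``run_id`` defaults to the
    file name without extension.  Non-numeric cells and a non-increasing
    size axis are rejected with the offending location named.
    """
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    if size_column not in frame.columns:
        raise ValueError(
            f"{path}: size column {size_column!r} not found; "
            f"columns are {list(frame.columns)}"
        )
    if run_id is None:
        run_id = os.path.splitext(os.path.basename(path))[0]
    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame[col].notna() & coerced.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric value {frame[col].iloc[row]!r} in "
                f"column {col!r}, data row {row}"
            )
        frame[col] = coerced
    sizes = frame[size_column].to_numpy(dtype=float)
    diffs = np.diff(sizes)
    if np.any(diffs <= 0):
        row = int(np.flatnonzero(diffs <= 0)[0]) + 1
        raise ValueError(
            f"{path}: size axis not strictly increasing at data row {row} "
            f"(size {sizes[row]:g})"
        )
    traces = []
    for col in frame.columns:
        if col == size_column:
            continue
        traces.append(
            Electropherogram(
                sample_id=str(col),
                run_id=run_id,
                sizes=sizes,
                rfu=frame[col].to_numpy(dtype=float),
            )
        )
    return traces


def read_runs(
    paths: Sequence[str], size_column: str = SIZE_COLUMN
) -> list[Electropherogram]:
    """Read several run files, rejecting sample-ID collisions across files."""
    seen: dict[str, str] = {}
    traces: list[Electropherogram] = []
    for path in paths:
        for trace in read_traces(path, size_column=size_column):
            if trace.sample_id in seen:
                raise ValueError(
                    f"duplicate sample ID {trace.sample_id!r} in {path} "
                    f"(already read from {seen[trace.sample_id]})"
                )
            seen[trace.sample_id] = path
            traces.append(trace)
    return traces


def write_traces(
    traces: Sequence[Electropherogram],
    path: str,
    size_column: str = SIZE_COLUMN,
    header_lines: Iterable[str] = (),
) -> None:
    """Write one run's traces as a wide CSV (shared size axis required)."""
    if not traces:
        raise ValueError("no traces to write")
    sizes = traces[0].sizes
    for trace in traces[1:]:
        if len(trace.sizes) != len(sizes) or not np.array_equal(trace.sizes, sizes):
            raise ValueError(
                f"trace {trace.sample_id!r} is not on the same size axis as "
                f"{traces[0].sample_id!r}; write runs separately"
            )
    data = {size_column: sizes}
    for trace in traces:
        if trace.sample_id in data:
            raise ValueError(f"duplicate sample ID {trace.sample_id!r}")
        data[trace.sample_id] = trace.rfu
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        pd.DataFrame(data).to_csv(fh, index=False)


@dataclass
class DesignTable:
    """A validated design table plus its balance diagnosis.

    ``balanced`` is True when the design is a complete crossing of
    solution x heat x temperature x time with the same replicate count in
    every cell — the condition under which sequential sums of squares
    coincide with the other SS types in the downstream ANOVA.
    """

    rows: list[SampleDesign]
    balanced: bool
    n_cells: int
    cell_counts: pd.Series

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def by_sample(self) -> dict[str, SampleDesign]:
        return {row.sample_id: row for row in self.rows}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows], columns=_DESIGN_COLUMNS)

    def reconcile(self, trace_sample_ids: Iterable[str]) -> dict[str, list[str]]:
        """Compare design rows with trace IDs; nothing is silently dropped.

        Returns lists of sample IDs present only in the design and only in
        the traces; both are logged.
        """
        trace_ids = set(trace_sample_ids)
        design_ids = {row.sample_id for row in self.rows}
        missing_traces = sorted(design_ids - trace_ids)
        missing_design = sorted(trace_ids - design_ids)
        for sid in missing_traces:
            logger.warning("design sample %r has no trace", sid)
        for sid in missing_design:
            logger.warning("trace sample %r has no design row", sid)
        return {"design_only": missing_traces, "traces_only": missing_design}


def _diagnose_balance(rows: Sequence[SampleDesign]) -> tuple[bool, int, pd.Series]:
    frame = pd.DataFrame(
        [(r.solution, r.heat, r.temperature, r.time_days) for r in rows],
        columns=["solution", "heat", "temperature", "time_days"],
    )
    counts = frame.value_counts()
    levels = [frame[c].nunique() for c in frame.columns]
    full_cells = int(np.prod(levels))
    balanced = len(counts) == full_cells and counts.nunique() == 1
    return balanced, len(counts), counts


def validate_design(rows: Sequence[SampleDesign]) -> DesignTable:
    """Validate uniqueness and diagnose balance of a set of design rows."""
    ids = pd.Series([r.sample_id for r in rows])
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample_id in design: {dup.iloc[0]!r}")
    balanced, n_cells, counts = _diagnose_balance(rows)
    return DesignTable(rows=list(rows), balanced=balanced, n_cells=n_cells,
                       cell_counts=counts)


def read_design(path: str) -> DesignTable:
    """Read and validate the sample-design metadata CSV.

    Unknown factor levels are rejected with the offending value and the
    allowed set named.  An incomplete crossing is *not* an error — the
    table's ``balanced`` flag records it.
    """
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in _DESIGN_COLUMNS if c not in frame.columns and c != "run_id"]
    if missing:
        raise ValueError(f"{path}: design table missing columns {missing}")
    if "run_id" not in frame.columns:
        frame["run_id"] = ""
    rows = [
        SampleDesign(
            sample_id=str(rec.sample_id),
            fish=str(rec.fish),
            solution=str(rec.solution),
            heat=str(rec.heat),
            temperature=str(rec.temperature),
            time_days=int(rec.time_days),
            run_id=str(rec.run_id),
        )
        for rec in frame.itertuples()
    ]
    return validate_design(rows)


def write_design(
    table: DesignTable | Sequence[SampleDesign],
    path: str,
    header_lines: Iterable[str] = (),
) -> None:
    rows = table.rows if isinstance(table, DesignTable) else list(table)
    frame = pd.DataFrame([vars(r) for r in rows], columns=_DESIGN_COLUMNS)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False)
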