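"""Cross-run harmonization of electropherograms.

Instrument runs report slightly different size-axis point estimates for
large fragments, so traces from different runs cannot be averaged directly.
The harmonization applies size-binning rules — sizes up to 1 kbp kept as
is, sizes in (1 kbp, 10 kbp] rounded up to the next multiple of 10 bp,
sizes above 10 kbp rounded half-up to the nearest 100 bp — averages RFU
within matching bins, clips negative RFU to zero, aligns all traces on the
union grid, and summarizes treatment groups as mean traces with 95%
confidence bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Electropherogram, SampleDesign, TREATMENT_FACTORS

logger = logging.getLogger(__name__)


def bin_sizes(sizes) -> np.ndarray:
    """Apply the size-binning rules to an array of fragment sizes (bp).

    <= 1,000 bp: unchanged.  (1,000, 10,000]: ceiling to the next multiple
    of 10.  > 10,000: half-up rounding to the nearest multiple of 100.
    The map is idempotent and monotone non-decreasing.
    """
    s = np.asarray(sizes, dtype=float)
    if np.any(s <= 0):
        raise ValueError("fragment sizes must be > 0")
    out = s.copy()
    mid = (s > 1000) & (s <= 10000)
    out[mid] = np.ceil(s[mid] / 10.0) * 10.0
    high = s > 10000
    out[high] = np.floor(s[high] / 100.0 + 0.5) * 100.0
    return out


def bin_size(size: float) -> float:
    """Scalar form of :func:`bin_sizes`."""
    return float(bin_sizes(np.array([size]))[0])


@dataclass
class MergedTrace:
    """One sample after binning, within-bin averaging and clipping."""

    sample_id: str
    run_id: str
    sizes: np.ndarray  # strictly increasing, on the binned grid
    rfu: np.ndarray    # all >= 0 after clipping


def merge_sample(trace: Electropherogram, clip_first: bool = False) -> MergedTrace:
    """Bin a trace's sizes, average RFU within bins, clip negatives to zero.

    ``clip_first`` clips negative RFU before within-bin averaging instead of
    after; the default follows the order bin -> average -> clip.
    """
    rfu = np.asarray(trace.rfu, dtype=float)
    if clip_first:
        rfu = np.clip(rfu, 0.0, None)
    binned = bin_sizes(trace.sizes)
    grid, inverse = np.unique(binned, return_inverse=True)
    sums = np.bincount(inverse, weights=rfu, minlength=len(grid))
    counts = np.bincount(inverse, minlength=len(grid))
    means = sums / counts
    means = np.clip(means, 0.0, None)
    return MergedTrace(trace.sample_id, trace.run_id, grid, means)


@dataclass
class AlignedTrace:
    """A merged trace re-expressed on the common union grid.

    ``rfu`` is NaN outside the trace's own observed size range (no
    extrapolation); ``interpolated`` marks in-range grid points that were
    filled by linear interpolation rather than observed directly.
    """

    sample_id: str
    run_id: str
    rfu: np.ndarray
    interpolated: np.ndarray  # bool mask, same length as the common grid


@dataclass
class AlignedSet:
    grid: np.ndarray
    traces: list[AlignedTrace]
    excluded: list[str]

    def __len__(self) -> int:
        return len(self.traces)


def align_runs(merged: Sequence[MergedTrace]) -> AlignedSet:
    """Place merged traces from all runs on their union size grid.

    Grid points inside a trace's observed range but absent from its own run
    are filled by linear interpolation between neighbours and flagged;
    points outside the observed range are NaN.  Traces with fewer than two
    points are excluded with a log entry.
    """
    if not merged:
        raise ValueError("no traces to align")
    usable = [m for m in merged if len(m.sizes) >= 2]
    excluded = [m.sample_id for m in merged if len(m.sizes) < 2]
    for sid in excluded:
        logger.warning("excluding trace %r from alignment: fewer than 2 points", sid)
    if not usable:
        raise ValueError("all traces excluded from alignment")
    grid = np.unique(np.concatenate([m.sizes for m in usable]))
    out = []
    for m in usable:
        values = np.interp(grid, m.sizes, m.rfu)
        in_range = (grid >= m.sizes[0]) & (grid <= m.sizes[-1])
        values[~in_range] = np.nan
        observed = np.isin(grid, m.sizes)
        out.append(
            AlignedTrace(m.sample_id, m.run_id, values, in_range & ~observed)
        )
    return AlignedSet(grid=grid, traces=out, excluded=excluded)


@dataclass
class GroupSummary:
    """Per-group mean trace with a pointwise 95% confidence band."""

    group_key: dict
    time_days: int
    sizes: np.ndarray
    mean_rfu: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_samples: int


def summarize_group(
    aligned: AlignedSet,
    designs: Sequence[SampleDesign],
    group_by: Sequence[str] = ("solution",),
    confidence: float = 0.95,
    ci_method: str = "t",
) -> list[GroupSummary]:
    """Mean RFU and confidence band per treatment group and time point.

    ``group_by`` is a subset of {solution, heat, temperature}; storage time
    is always a grouping variable on top of it.  The band is
    mean +/- t(1-(1-confidence)/2, n-1) * SD/sqrt(n) per grid point
    (``ci_method="normal"`` swaps the t quantile for the normal one).
    Groups with a single member get a degenerate band equal to the mean.
    """
    bad = [g for g in group_by if g not in TREATMENT_FACTORS]
    if bad:
        raise ValueError(
            f"group_by entries must be treatment factors {TREATMENT_FACTORS}; got {bad}"
        )
    design_by_id = {d.sample_id: d for d in designs}
    missing = [t.sample_id for t in aligned.traces if t.sample_id not in design_by_id]
    if missing:
        raise ValueError(f"traces without design rows: {missing[:5]}")

    groups: dict[tuple, list[AlignedTrace]] = {}
    for trace in aligned.traces:
        design = design_by_id[trace.sample_id]
        key = tuple(getattr(design, g) for g in group_by) + (design.time_days,)
        groups.setdefault(key, []).append(trace)

    summaries = []
    for key in sorted(groups):
        members = groups[key]
        matrix = np.vstack([t.rfu for t in members])
        n_pt = np.sum(~np.isnan(matrix), axis=0)
        # grid points observed by no member (outside every trace's range)
        # stay NaN; masked arrays avoid empty-slice warnings
        masked = np.ma.masked_invalid(matrix)
        mean = np.ma.filled(masked.mean(axis=0), np.nan)
        half = np.zeros_like(mean)
        multi = n_pt > 1
        if np.any(multi):
            sd = np.ma.filled(masked.std(axis=0, ddof=1), np.nan)
            alpha = 1.0 - confidence
            if ci_method == "t":
                q = stats.t.ppf(1 - alpha / 2, np.where(multi, n_pt - 1, 1))
            elif ci_method == "normal":
                q = np.full_like(mean, stats.norm.ppf(1 - alpha / 2))
            else:
                raise ValueError(f"unknown ci_method {ci_method!r}")
            half = np.where(multi, q * sd / np.sqrt(n_pt), 0.0)
        summaries.append(
            GroupSummary(
                group_key=dict(zip(group_by, key[:-1])),
                time_days=int(key[-1]),
                sizes=aligned.grid,
                mean_rfu=mean,
                ci_low=mean - half,
                ci_high=mean + half,
                n_samples=len(members),
            )
        )
    return summaries


def summaries_to_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    """Tidy long-format view: one row per group x time x grid point."""
    frames = []
    for s in summaries:
        frame = pd.DataFrame(
            {
                "size_bp": s.sizes,
                "mean_rfu": s.mean_rfu,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
            }
        )
        for name, value in s.group_key.items():
            frame.insert(0, name, value)
        frame.insert(len(s.group_key), "time_days", s.time_days)
        frame["n"] = s.n_samples
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
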