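"""High-molecular-weight (HMW) DNA quantification.

DNA mass in a size window is proxied by the area under the RFU-versus-size
curve (trapezoidal rule).  Sizes below 250 bp are excluded to avoid RNA
carry-over inflating the total; HMW is the area at or above 20 kbp.  Each
group's HMW area is reported raw (as a percentage of its own total) and
standardized (as a percentage of the single largest HMW area across all
groups, which scores 100 by construction).  The DESS/ETOH scale factor is
the ratio of standardized percentages between the two storage solutions at
each time point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .merge import GroupSummary

logger = logging.getLogger(__name__)

HMW_THRESHOLD_BP = 20_000.0
RNA_EXCLUSION_BP = 250.0


def auc(sizes, rfu, lo: float = RNA_EXCLUSION_BP, hi: float = np.inf) -> float:
    """Trapezoidal area under the trace over the size window [lo, hi].

    The window is intersected with the observed range; a cut point that
    falls between grid points enters via linear interpolation of the
    integrand.  NaN points (unobserved after alignment) are dropped first.
    A window disjoint from the observed range yields 0 with a warning.
    """
    s = np.asarray(sizes, dtype=float)
    y = np.asarray(rfu, dtype=float)
    keep = ~(np.isnan(s) | np.isnan(y))
    s, y = s[keep], y[keep]
    if len(s) < 2:
        logger.warning("auc: fewer than 2 observed points; area set to 0")
        return 0.0
    if np.any(np.diff(s) <= 0):
        raise ValueError("auc: sizes must be strictly increasing")
    if not lo < hi:
        raise ValueError(f"auc: empty window [{lo}, {hi}]")
    lo_eff = max(lo, s[0])
    hi_eff = min(hi, s[-1])
    if lo_eff >= hi_eff:
        logger.warning(
            "auc: window [%g, %g] disjoint from observed range [%g, %g]",
            lo, hi, s[0], s[-1],
        )
        return 0.0
    inside = (s > lo_eff) & (s < hi_eff)
    xs = np.concatenate(([lo_eff], s[inside], [hi_eff]))
    ys = np.concatenate(
        ([np.interp(lo_eff, s, y)], y[inside], [np.interp(hi_eff, s, y)])
    )
    return float(np.trapezoid(ys, xs))


@dataclass
class HMWReport:
    """AUC-based HMW content of one group at one time point."""

    group_key: dict
    time_days: int
    total_auc: float        # area over sizes >= the RNA exclusion
    hmw_auc: float          # area over sizes >= the HMW threshold
    raw_pct: float | None   # 100 * hmw/total; None when total is 0
    std_pct: float          # 100 * hmw / max(hmw) over all groups
    is_reference: bool = False

    @property
    def label(self) -> str:
        parts = [str(v) for v in self.group_key.values()]
        parts.append(f"{self.time_days}d")
        return "-".join(parts)


def hmw_report(
    summaries: Sequence[GroupSummary],
    hmw_threshold: float = HMW_THRESHOLD_BP,
    min_size: float = RNA_EXCLUSION_BP,
) -> list[HMWReport]:
    """Quantify HMW content for every group x time summary.

    The standardization reference is the single group x time entry with the
    globally maximal HMW AUC; it scores std_pct = 100 exactly.  Ties are
    broken by the deterministic (group key, time) sort order and logged.
    """
    if not summaries:
        raise ValueError("no group summaries given")
    entries = sorted(
        summaries, key=lambda s: (tuple(s.group_key.items()), s.time_days)
    )
    reports = []
    for s in entries:
        total = auc(s.sizes, s.mean_rfu, lo=min_size)
        hmw = auc(s.sizes, s.mean_rfu, lo=max(hmw_threshold, min_size))
        raw = 100.0 * hmw / total if total > 0 else None
        if raw is None:
            logger.warning("group %s: zero total AUC; raw_pct missing",
                           dict(s.group_key, time_days=s.time_days))
        reports.append(
            HMWReport(
                group_key=dict(s.group_key),
                time_days=s.time_days,
                total_auc=total,
                hmw_auc=hmw,
                raw_pct=raw,
                std_pct=np.nan,
            )
        )
    hmw_values = np.array([r.hmw_auc for r in reports])
    ref = int(np.argmax(hmw_values))
    if np.sum(hmw_values == hmw_values[ref]) > 1:
        logger.warning(
            "HMW standardization reference tie broken deterministically in "
            "favour of %s", reports[ref].label,
        )
    ref_auc = hmw_values[ref]
    for i, r in enumerate(reports):
        r.std_pct = 100.0 * r.hmw_auc / ref_auc if ref_auc > 0 else np.nan
        r.is_reference = i == ref
    return reports


def reports_to_frame(reports: Sequence[HMWReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = dict(r.group_key)
        row.update(
            time_days=r.time_days,
            total_auc=r.total_auc,
            hmw_auc=r.hmw_auc,
            raw_pct=r.raw_pct,
            std_pct=r.std_pct,
            is_reference=r.is_reference,
        )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ScaleFactorTable:
    """Per-time-point DESS/ETOH ratio of standardized HMW percentages.

    Full precision is retained in ``table``; :meth:`rounded` gives the
    1-decimal reporting view.
    """

    table: pd.DataFrame  # time_days, std_pct_DESS, std_pct_ETOH, ratio

    def rounded(self, decimals: int = 1) -> pd.DataFrame:
        return self.table.round(
            {"std_pct_DESS": decimals, "std_pct_ETOH": decimals, "ratio": decimals}
        )


def scale_factors(reports: Sequence[HMWReport]) -> ScaleFactorTable:
    """DESS/ETOH scale factor per time point from solution-level reports.

    Inputs must be grouped by solution only.  A time point missing one
    solution, or with a zero ETOH percentage, gets a missing ratio rather
    than an error.
    """
    for r in reports:
        if set(r.group_key) != {"solution"}:
            raise ValueError(
                "scale_factors needs reports grouped by solution only; "
                f"got group key {sorted(r.group_key)}"
            )
    by_time: dict[int, dict[str, float]] = {}
    for r in reports:
        by_time.setdefault(r.time_days, {})[r.group_key["solution"]] = r.std_pct
    rows = []
    for t in sorted(by_time):
        dess = by_time[t].get("DESS", np.nan)
        etoh = by_time[t].get("ETOH", np.nan)
        if np.isnan(dess) or np.isnan(etoh):
            logger.warning("time %d d: missing solution; scale factor omitted", t)
        ratio = dess / etoh if etoh and etoh > 0 else np.nan
        rows.append(
            {"time_days": t, "std_pct_DESS": dess, "std_pct_ETOH": etoh,
             "ratio": ratio}
        )
    return ScaleFactorTable(pd.DataFrame(rows))
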