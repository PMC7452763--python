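"""Fragmentation scoring and the factorial ANOVA over the storage design.

The fragmentation score is a documented surrogate for the instrument
software's proprietary Genomic Quality Number (GQN): 10 times the fraction
of integrated signal at or above a user-set size threshold, among signal at
or above the RNA-exclusion size.  Like the GQN it lives on a 0-10 scale and
is invariant to the overall signal amplitude.

The ANOVA fits the fixed-effects linear model with solution, heat
treatment, storage temperature and storage time (categorical) and all
their interactions, decomposing variance with sequential (type-I) sums of
squares in the canonical order: main effects, then interactions by
ascending order.  On a complete balanced crossing this coincides with
type-II/III, which the fit asserts rather than assumes.  A partial F test
compares the full model against a nested reduction (e.g., solution only).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .hmw import RNA_EXCLUSION_BP, auc
from .merge import MergedTrace

GQN_THRESHOLD_BP = 10_000.0

_FACTORS = ("solution", "heat", "temperature", "time_days")
_SHORT = {"solution": "solution", "heat": "heat",
          "temperature": "temp", "time_days": "time"}


@dataclass
class QualityScore:
    sample_id: str
    gqn_surrogate: float  # in [0, 10]; NaN when the trace has no signal
    threshold: float
    min_size: float


def gqn_surrogate(
    sizes,
    rfu,
    threshold: float = GQN_THRESHOLD_BP,
    min_size: float = RNA_EXCLUSION_BP,
) -> float:
    """Score fragmentation on a 0-10 scale.

    10 x (area at or above ``threshold``) / (area at or above ``min_size``).
    Returns NaN when the trace carries no signal above ``min_size``.
    Negative RFU should have been clipped upstream (merge stage); the score
    is clamped to [0, 10] against residual numerical noise.
    """
    if threshold < min_size:
        raise ValueError("threshold must be >= min_size")
    total = auc(sizes, rfu, lo=min_size)
    if total <= 0:
        return float("nan")
    above = auc(sizes, rfu, lo=threshold)
    return float(np.clip(10.0 * above / total, 0.0, 10.0))


def score_samples(
    traces: Sequence[MergedTrace],
    threshold: float = GQN_THRESHOLD_BP,
    min_size: float = RNA_EXCLUSION_BP,
) -> pd.DataFrame:
    """Per-sample fragmentation scores as a tidy frame."""
    rows = [
        {
            "sample_id": t.sample_id,
            "gqn_surrogate": gqn_surrogate(t.sizes, t.rfu, threshold, min_size),
            "threshold": threshold,
            "min_size": min_size,
        }
        for t in traces
    ]
    return pd.DataFrame(rows)


def canonical_terms(factors: Sequence[str] = _FACTORS) -> list[tuple[str, ...]]:
    """Main effects, then 2-, 3-, ... way interactions in canonical order.

    Within each interaction order, terms appear in the order generated by
    expanding the crossed product left to right (solution:heat,
    solution:temp, heat:temp, solution:time, ...), matching the
    conventional ANOVA table layout for a crossed design.
    """
    terms: list[tuple[str, ...]] = [(f,) for f in factors]
    for order in range(2, len(factors) + 1):
        block = []
        for combo in combinations(factors, order):
            block.append(combo)
        # expansion order: interactions involving later-introduced factors last
        block.sort(key=lambda c: tuple(factors.index(f) for f in reversed(c)))
        terms.extend(block)
    return terms


def term_label(term: tuple[str, ...]) -> str:
    return ":".join(_SHORT[f] for f in term)


@dataclass
class AnovaResult:
    """Term-wise sequential ANOVA decomposition of the factorial model."""

    table: pd.DataFrame          # term, df, sum_sq, F, p_value
    resid_df: int
    resid_ss: float
    total_ss: float
    nobs: int
    terms: tuple[tuple[str, ...], ...]
    response: str
    ss_type_consistent: bool | None  # type-I == type-II (balanced designs)

    def p_value(self, label: str) -> float:
        row = self.table.loc[self.table["term"] == label]
        if row.empty:
            raise KeyError(f"no term {label!r} in the model")
        return float(row["p_value"].iloc[0])

    def to_frame(self, stars: bool = True) -> pd.DataFrame:
        out = self.table.copy()
        if stars:
            out["signif"] = [
                "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
                if np.isfinite(p) else ""
                for p in out["p_value"]
            ]
        resid = pd.DataFrame(
            [{"term": "Residual", "df": self.resid_df, "sum_sq": self.resid_ss,
              "F": np.nan, "p_value": np.nan}]
        )
        return pd.concat([out, resid], ignore_index=True)


def _patsy_term(term: tuple[str, ...]) -> str:
    return ":".join(f"C({f})" for f in term)


def _check_cells(data: pd.DataFrame, terms: Sequence[tuple[str, ...]]) -> None:
    factors = sorted({f for t in terms for f in t}, key=_FACTORS.index)
    if len(factors) < 2:
        return
    counts = data.groupby(factors, observed=True).size()
    full = int(np.prod([data[f].nunique() for f in factors]))
    max_order = max(len(t) for t in terms)
    if max_order == len(factors) and len(counts) < full:
        raise ValueError(
            f"design has {full - len(counts)} empty cells; the full "
            "interaction model is rank deficient — drop the highest-order "
            "interaction terms or complete the design"
        )


def factorial_anova(
    scores: pd.DataFrame,
    designs: pd.DataFrame,
    terms: str | Sequence[tuple[str, ...]] = "full",
    response: str = "gqn_surrogate",
    check_balanced: bool = True,
) -> AnovaResult:
    """Fit the factorial ANOVA of the storage experiment.

    ``scores`` carries sample_id and the response column; ``designs`` the
    factor levels.  ``terms`` is "full" (all main effects and interactions
    of solution, heat, temperature, time) or an explicit ordered list of
    factor tuples.  Sums of squares are sequential in the given order; when
    the design is a complete balanced crossing the result is additionally
    checked to agree with type-II SS (``ss_type_consistent``).
    """
    if terms == "full":
        term_list = canonical_terms()
    elif terms == "solution":
        term_list = [("solution",)]
    else:
        term_list = [tuple(t) if not isinstance(t, str) else (t,) for t in terms]
    for t in term_list:
        for f in t:
            if f not in _FACTORS:
                raise ValueError(f"unknown factor {f!r}; choose from {_FACTORS}")

    data = scores.merge(designs, on="sample_id", how="inner", validate="1:1")
    unmatched = len(scores) - len(data)
    if unmatched:
        raise ValueError(f"{unmatched} scored samples have no design row")
    data = data.dropna(subset=[response])
    _check_cells(data, term_list)

    rhs = " + ".join(_patsy_term(t) for t in term_list)
    model = smf.ols(f"{response} ~ {rhs}", data=data).fit()
    with np.errstate(invalid="ignore", divide="ignore"):
        anova1 = sm.stats.anova_lm(model, typ=1)

    # a response constant to rounding error makes every mean square 0/0;
    # F and p are then undefined and reported missing
    y_all = data[response].to_numpy(dtype=float)
    scale = float(np.sum(y_all**2))
    degenerate = float(anova1.loc["Residual", "sum_sq"]) <= 1e-24 * max(scale, 1e-300)

    rows = []
    for t in term_list:
        key = _patsy_term(t)
        rec = anova1.loc[key]
        f_val = np.nan if degenerate else float(rec["F"])
        p_val = np.nan if degenerate else float(rec["PR(>F)"])
        rows.append(
            {
                "term": term_label(t),
                "df": int(rec["df"]),
                "sum_sq": float(rec["sum_sq"]),
                "F": f_val if np.isfinite(f_val) else np.nan,
                "p_value": p_val if np.isfinite(p_val) else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    resid = anova1.loc["Residual"]

    consistent = None
    if check_balanced:
        cell_counts = data.groupby(
            [f for f in _FACTORS if any(f in t for t in term_list)],
            observed=True,
        ).size()
        if cell_counts.nunique() == 1:
            with np.errstate(invalid="ignore", divide="ignore"):
                anova2 = sm.stats.anova_lm(model, typ=2)
            ss1 = table["sum_sq"].to_numpy()
            ss2 = np.array(
                [float(anova2.loc[_patsy_term(t), "sum_sq"]) for t in term_list]
            )
            scale = max(float(np.max(np.abs(ss1))), 1e-12)
            consistent = bool(np.allclose(ss1, ss2, rtol=1e-6, atol=1e-8 * scale))
            if not consistent:
                raise AssertionError(
                    "sequential and type-II sums of squares disagree on a "
                    "balanced design; check the design table"
                )

    y = data[response].to_numpy(dtype=float)
    total_ss = float(np.sum((y - y.mean()) ** 2))
    return AnovaResult(
        table=table,
        resid_df=int(resid["df"]),
        resid_ss=float(resid["sum_sq"]),
        total_ss=total_ss,
        nobs=len(data),
        terms=tuple(term_list),
        response=response,
        ss_type_consistent=consistent,
    )


@dataclass
class ModelComparison:
    f_stat: float
    df_num: int
    df_den: int
    p_value: float


def compare_models(full: AnovaResult, reduced: AnovaResult) -> ModelComparison:
    """Partial F test of a nested reduction against the full model.

    F = [(SSR_reduced - SSR_full) / (df_reduced - df_full)] / MS_resid_full.
    An identical pair gives F = 0, p = 1.
    """
    if full.nobs != reduced.nobs or full.response != reduced.response:
        raise ValueError("models were fit to different data")
    if not set(reduced.terms) <= set(full.terms):
        raise ValueError("models are not nested: reduced terms must be a "
                         "subset of the full model's terms")
    df_num = reduced.resid_df - full.resid_df
    if df_num == 0:
        return ModelComparison(0.0, 0, full.resid_df, 1.0)
    ss_gain = max(reduced.resid_ss - full.resid_ss, 0.0)
    ms_full = full.resid_ss / full.resid_df
    f_stat = (ss_gain / df_num) / ms_full
    p = float(stats.f.sf(f_stat, df_num, full.resid_df))
    return ModelComparison(float(f_stat), int(df_num), int(full.resid_df), p)
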