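"""Fragmentation score and factorial ANOVA against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fragqc import compare_models, factorial_anova, gqn_surrogate, score_samples
from fragqc.merge import MergedTrace


def test_gqn_bounds_and_symmetry():
    # signal entirely above / below the threshold (clear of the 10 kbp cut,
    # so the trapezoid ramps at the rectangle edges cancel exactly)
    sizes = np.linspace(250, 20_250, 2001)
    all_above = np.where(sizes >= 15_000, 1.0, 0.0)
    assert gqn_surrogate(sizes, all_above) == pytest.approx(10.0, rel=1e-12)
    all_below = np.where(sizes <= 5_000, 1.0, 0.0)
    assert gqn_surrogate(sizes, all_below) == pytest.approx(0.0, abs=1e-12)
    # two equal rectangles straddling the threshold -> 5
    sizes = np.linspace(250, 19_750, 2001)  # symmetric around 10,000
    assert gqn_surrogate(sizes, np.ones_like(sizes)) == pytest.approx(5.0, rel=1e-9)


def test_gqn_zero_signal_is_missing():
    assert np.isnan(gqn_surrogate([300.0, 400.0], [0.0, 0.0]))


def test_gqn_threshold_below_min_size_rejected():
    with pytest.raises(ValueError):
        gqn_surrogate([300.0, 400.0], [1.0, 1.0], threshold=100, min_size=250)


def test_score_samples_amplitude_invariance():
    sizes = np.geomspace(250, 60_000, 200)
    rfu = np.exp(-0.5 * ((np.log(sizes) - np.log(5_000)) / 0.8) ** 2)
    traces = [MergedTrace("a", "r", sizes, rfu),
              MergedTrace("b", "r", sizes, 7.3 * rfu)]
    scores = score_samples(traces)
    assert scores["gqn_surrogate"].iloc[0] == pytest.approx(
        scores["gqn_surrogate"].iloc[1], rel=1e-12)


def _frame_2x2(cell_means, n, noise_sd=0.0, seed=0):
    """Balanced 2x2 (solution x heat) with known cell means."""
    rng = np.random.default_rng(seed)
    scores, designs = [], []
    i = 0
    for sol in ("DESS", "ETOH"):
        for heat in ("treated", "untreated"):
            for _ in range(n):
                sid = f"s{i}"; i += 1
                scores.append({"sample_id": sid,
                               "gqn_surrogate": cell_means[(sol, heat)]
                               + rng.normal(0, noise_sd)})
                designs.append({"sample_id": sid, "solution": sol, "heat": heat})
    return pd.DataFrame(scores), pd.DataFrame(designs)


def _projection_ss_2x2(values):
    """Direct-projection sums of squares for a balanced 2x2 layout.

    ``values`` is an (2, 2, n) array indexed (solution, heat, replicate).
    """
    grand = values.mean()
    n = values.shape[2]
    mean_a = values.mean(axis=(1, 2))
    mean_b = values.mean(axis=(0, 2))
    mean_ab = values.mean(axis=2)
    ss_a = 2 * n * np.sum((mean_a - grand) ** 2)
    ss_b = 2 * n * np.sum((mean_b - grand) ** 2)
    interaction = mean_ab - mean_a[:, None] - mean_b[None, :] + grand
    ss_ab = n * np.sum(interaction ** 2)
    ss_resid = np.sum((values - mean_ab[:, :, None]) ** 2)
    return ss_a, ss_b, ss_ab, ss_resid


TERMS_2X2 = [("solution",), ("heat",), ("solution", "heat")]


def test_balanced_2x2_matches_projection_oracle_exactly():
    cell_means = {("DESS", "treated"): 8.0, ("DESS", "untreated"): 6.5,
                  ("ETOH", "treated"): 3.0, ("ETOH", "untreated"): 1.0}
    scores, designs = _frame_2x2(cell_means, n=4)
    result = factorial_anova(scores, designs, terms=TERMS_2X2)
    values = scores["gqn_surrogate"].to_numpy().reshape(2, 2, 4)
    ss_a, ss_b, ss_ab, ss_resid = _projection_ss_2x2(values)
    table = dict(zip(result.table["term"], result.table["sum_sq"]))
    assert table["solution"] == pytest.approx(ss_a, rel=1e-10, abs=1e-10)
    assert table["heat"] == pytest.approx(ss_b, rel=1e-10, abs=1e-10)
    assert table["solution:heat"] == pytest.approx(ss_ab, rel=1e-10, abs=1e-10)
    assert result.resid_ss == pytest.approx(ss_resid, abs=1e-10)
    assert result.ss_type_consistent


def test_noisy_2x2_ss_decomposition_sums_to_total():
    cell_means = {("DESS", "treated"): 5.0, ("DESS", "untreated"): 4.0,
                  ("ETOH", "treated"): 2.0, ("ETOH", "untreated"): 2.5}
    scores, designs = _frame_2x2(cell_means, n=6, noise_sd=1.0, seed=3)
    result = factorial_anova(scores, designs, terms=TERMS_2X2)
    decomposed = result.table["sum_sq"].sum() + result.resid_ss
    assert decomposed == pytest.approx(result.total_ss, rel=1e-10)
    # model + residual df account for every observation
    assert result.table["df"].sum() + result.resid_df == result.nobs - 1


def test_single_factor_f_equals_squared_t():
    rng = np.random.default_rng(11)
    a, b = rng.normal(5, 1, 12), rng.normal(6, 1, 12)
    scores = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(24)],
        "gqn_surrogate": np.concatenate([a, b]),
    })
    designs = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(24)],
        "solution": ["DESS"] * 12 + ["ETOH"] * 12,
    })
    result = factorial_anova(scores, designs, terms=[("solution",)])
    t_stat, t_p = stats.ttest_ind(a, b, equal_var=True)
    assert result.table["F"].iloc[0] == pytest.approx(t_stat**2, rel=1e-10)
    assert result.table["p_value"].iloc[0] == pytest.approx(t_p, rel=1e-10)


def test_constant_response_reports_missing_f():
    cell_means = {k: 4.0 for k in
                  [("DESS", "treated"), ("DESS", "untreated"),
                   ("ETOH", "treated"), ("ETOH", "untreated")]}
    scores, designs = _frame_2x2(cell_means, n=3)
    result = factorial_anova(scores, designs, terms=TERMS_2X2)
    assert np.allclose(result.table["sum_sq"], 0.0, atol=1e-20)
    assert result.resid_ss == pytest.approx(0.0, abs=1e-20)
    assert result.table["F"].isna().all()
    assert result.table["p_value"].isna().all()


def test_term_order_immaterial_on_balanced_design(small_dataset):
    from fragqc import merge_sample
    merged = [merge_sample(t) for t in small_dataset.traces[:80]]
    # restrict to time 1 & 7 (first two runs) for a quick balanced subset
    scores = score_samples(merged)
    designs = small_dataset.design.to_frame()
    terms = [("solution",), ("temperature",), ("solution", "temperature")]
    forward = factorial_anova(scores, designs, terms=terms)
    backward = factorial_anova(scores, designs, terms=list(reversed(terms)))
    fwd = dict(zip(forward.table["term"], forward.table["sum_sq"]))
    bwd = dict(zip(backward.table["term"], backward.table["sum_sq"]))
    for label, value in fwd.items():
        assert bwd[label] == pytest.approx(value, rel=1e-8)


def test_missing_cell_with_full_interactions_raises():
    cell_means = {("DESS", "treated"): 5.0, ("DESS", "untreated"): 4.0,
                  ("ETOH", "treated"): 2.0, ("ETOH", "untreated"): 2.5}
    scores, designs = _frame_2x2(cell_means, n=3)
    keep = designs["heat"].eq("treated") | designs["solution"].eq("DESS")
    with pytest.raises(ValueError, match="empty cells"):
        factorial_anova(scores[keep.values], designs[keep.values], terms=TERMS_2X2)


def test_compare_identical_models_is_null():
    cell_means = {("DESS", "treated"): 5.0, ("DESS", "untreated"): 4.0,
                  ("ETOH", "treated"): 2.0, ("ETOH", "untreated"): 2.5}
    scores, designs = _frame_2x2(cell_means, n=4, noise_sd=0.5, seed=1)
    full = factorial_anova(scores, designs, terms=TERMS_2X2)
    result = compare_models(full, full)
    assert result.f_stat == 0.0 and result.p_value == 1.0


def test_partial_f_matches_statsmodels_oracle():
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    cell_means = {("DESS", "treated"): 5.0, ("DESS", "untreated"): 4.2,
                  ("ETOH", "treated"): 2.0, ("ETOH", "untreated"): 2.6}
    scores, designs = _frame_2x2(cell_means, n=5, noise_sd=0.8, seed=9)
    full = factorial_anova(scores, designs, terms=TERMS_2X2)
    reduced = factorial_anova(scores, designs, terms=[("solution",)])
    ours = compare_models(full, reduced)

    data = scores.merge(designs, on="sample_id")
    m_red = smf.ols("gqn_surrogate ~ C(solution)", data=data).fit()
    m_full = smf.ols(
        "gqn_surrogate ~ C(solution) + C(heat) + C(solution):C(heat)", data=data
    ).fit()
    oracle = anova_lm(m_red, m_full)
    assert ours.f_stat == pytest.approx(float(oracle["F"].iloc[1]), rel=1e-10)
    assert ours.p_value == pytest.approx(float(oracle["Pr(>F)"].iloc[1]), rel=1e-10)


def test_non_nested_models_rejected():
    cell_means = {("DESS", "treated"): 5.0, ("DESS", "untreated"): 4.0,
                  ("ETOH", "treated"): 2.0, ("ETOH", "untreated"): 2.5}
    scores, designs = _frame_2x2(cell_means, n=4, noise_sd=0.5, seed=2)
    a = factorial_anova(scores, designs, terms=[("solution",)])
    b = factorial_anova(scores, designs, terms=[("heat",)])
    with pytest.raises(ValueError, match="nested"):
        compare_models(a, b)
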