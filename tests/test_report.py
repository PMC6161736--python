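"""Aggregation tables, dCt expression, correlation, splicing bias, Sanger ratios."""

import math

import numpy as np
import pytest

from ampliedit.reference import SampleMeta
from ampliedit.report import (
    aggregate_editing,
    correlate_editing_expression,
    delta_ct,
    expression_table,
    sanger_rate,
    splicing_bias,
)
from ampliedit.simulate import (
    SimulationConfig,
    expected_pool_rates,
    simulate_sanger_peaks,
    simulate_site_counts,
)
from oracles import ols_normal_equations


def meta(tissue, tp, rep):
    return SampleMeta(f"{tissue}-{tp}-{rep}", tissue, tp, rep)


def test_aggregate_mean_and_sd():
    rows = [(meta("femur", "P120", i + 1), r) for i, r in enumerate([0.70, 0.75, 0.80])]
    table = aggregate_editing(rows)
    assert len(table) == 1
    assert table["mean"][0] == pytest.approx(0.75)
    assert table["sd"][0] == pytest.approx(0.05, abs=1e-12)  # n-1 denominator
    assert table["n"][0] == 3 and not table["single_replicate"][0]


def test_aggregate_single_replicate_flagged():
    table = aggregate_editing([(meta("skin", "P0", 1), 0.4)])
    assert table["mean"][0] == 0.4
    assert table["sd"][0] == 0.0 and table["single_replicate"][0]


def test_aggregate_equal_replicates_sd_zero():
    rows = [(meta("heart", "P21", i + 1), 0.66) for i in range(3)]
    assert aggregate_editing(rows)["sd"][0] == 0.0


def test_aggregate_excludes_missing_and_orders_timepoints():
    rows = [
        (meta("aorta", "P120", 1), 0.6),
        (meta("aorta", "P120", 2), math.nan),
        (meta("aorta", "P0", 1), 0.2),
        (meta("aorta", "P21", 1), 0.4),
    ]
    table = aggregate_editing(rows)
    assert list(table["timepoint"]) == ["P0", "P21", "P120"]
    p120 = table[table["timepoint"] == "P120"].iloc[0]
    assert p120["n"] == 1 and p120["n_missing"] == 1
    assert min(r for row in table["rates"] for r in row) >= 0.2


@pytest.mark.parametrize(
    "ct_t, ct_r, expected",
    [(20.0, 20.0, 1.0), (21.0, 20.0, 0.5), (17.5, 20.0, 2.0**2.5)],
)
def test_delta_ct_closed_form(ct_t, ct_r, expected):
    assert delta_ct(ct_t, ct_r) == pytest.approx(expected, rel=1e-12)


def test_delta_ct_missing_is_nan():
    assert math.isnan(delta_ct(math.nan, 20.0))


def test_correlation_exact_line():
    pairs = [(0.1 + 0.2 * x, float(x)) for x in range(5)]
    fit = correlate_editing_expression(pairs)
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.slope == pytest.approx(0.2)


def test_correlation_permutation_invariant(rng):
    pairs = [(float(r), float(e)) for r, e in rng.random((10, 2))]
    f1 = correlate_editing_expression(pairs)
    shuffled = [pairs[i] for i in rng.permutation(10)]
    f2 = correlate_editing_expression(shuffled)
    assert f1.slope == pytest.approx(f2.slope)
    assert f1.r_squared == pytest.approx(f2.r_squared)


def test_correlation_matches_normal_equations_oracle(rng):
    x = rng.random(10)
    y = 0.3 + 0.5 * x + rng.normal(0, 0.05, 10)
    fit = correlate_editing_expression(list(zip(y, x)))
    slope_o, intercept_o, r2_o = ols_normal_equations(x, y)
    assert fit.slope == pytest.approx(slope_o, abs=1e-9)
    assert fit.intercept == pytest.approx(intercept_o, abs=1e-9)
    assert fit.r_squared == pytest.approx(r2_o, abs=1e-9)


def test_correlation_zero_variance_flagged():
    fit = correlate_editing_expression([(0.1, 2.0), (0.2, 2.0), (0.3, 2.0)])
    assert not fit.ok and math.isnan(fit.slope)


def test_correlation_needs_three_pairs():
    with pytest.raises(ValueError):
        correlate_editing_expression([(0.1, 1.0), (0.2, 2.0)])


def test_splicing_bias_closed_forms():
    assert splicing_bias(0.5, 0.5).odds_ratio == pytest.approx(1.0)
    assert splicing_bias(0.8, 0.5).odds_ratio == pytest.approx(0.25)


def test_splicing_bias_degenerate_bounded():
    out = splicing_bias(0.8, 0.0)
    assert out.bounded and math.isfinite(out.odds_ratio)
    with pytest.raises(ValueError):
        splicing_bias(1.2, 0.5)


def test_splicing_bias_negative_under_selection():
    """Generative consistency: positive splicing penalties give OR < 1."""
    cfg = SimulationConfig(seed=0)  # defaults carry positive penalties
    rates = expected_pool_rates(cfg)
    out = splicing_bias(rates["pre_mrna"]["Q/R"], rates["mrna"]["Q/R"])
    assert out.odds_ratio < 1.0


@pytest.mark.parametrize("a, g, expected", [(100.0, 0.0, 0.0), (50.0, 50.0, 0.5)])
def test_sanger_rate_closed_form(a, g, expected):
    assert sanger_rate(a, g) == expected


def test_sanger_rate_both_zero_missing():
    assert math.isnan(sanger_rate(0.0, 0.0))


def test_sanger_rate_recovers_simulated_truth():
    est = [sanger_rate(*simulate_sanger_peaks(0.3, 0.05, seed=i)) for i in range(200)]
    assert abs(np.mean(est) - 0.3) < 0.02


def test_expression_table():
    import pandas as pd

    ct = pd.DataFrame(
        {"sample_id": ["a"], "ct_target": [22.0], "ct_reference": [20.0]}
    )
    out = expression_table(ct)
    assert out["relative_expression"][0] == pytest.approx(0.25)


def test_amplicon_beats_sanger_at_low_rates():
    """At true rates < 0.05, read-counting estimates have strictly smaller
    RMSE than peak-ratio estimates at matched noise settings."""
    rng = np.random.default_rng(99)
    true = 0.03
    amp_err, sang_err = [], []
    for i in range(100):
        sc = simulate_site_counts(true, 7824, 0.001, rng)
        amp_err.append((sc.g / sc.depth - true) ** 2)
        a, g = simulate_sanger_peaks(true, noise_sd=0.03, seed=1000 + i)
        sang_err.append((sanger_rate(a, g) - true) ** 2)
    assert math.sqrt(np.mean(amp_err)) < math.sqrt(np.mean(sang_err))


def test_end_to_end_age_trend(flnb_ref):
    """A simulated design with age-increasing true rates reproduces the
    monotone trend in the aggregated tissue table."""
    from ampliedit.demux import demultiplex
    from ampliedit.quantify import quantify_sample
    from ampliedit.simulate import random_sample_sheet, simulate_study

    sheet = random_sample_sheet(
        12, seed=7, tissues=["cortex", "femur"], replicates=2
    )
    true_by_tp = {"P0": 0.10, "P21": 0.35, "P120": 0.65}
    configs = {
        m.sample_id: SimulationConfig(
            depth_mean=400.0, depth_dispersion=1e6, error_rate=0.001,
            editing_marginals=(0.1, true_by_tp[m.timepoint], 0.2),
            splice_penalty_qr=0.0, splice_penalty_intron=0.0,
        )
        for m, _ in sheet
    }
    reads, truths = simulate_study(flnb_ref, sheet, configs, seed=7, n_molecules=4000)
    per, report = demultiplex(reads, sheet, max_mismatch=1)
    pairs = []
    for m, _ in sheet:
        q = quantify_sample(per[m.sample_id], flnb_ref, sample_id=m.sample_id)
        pairs.append((m, q.estimates["Q/R"].rate))
    table = aggregate_editing(pairs)
    for tissue in ("cortex", "femur"):
        means = table[table["tissue"] == tissue]["mean"].tolist()
        assert means == sorted(means)  # P0 < P21 < P120
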