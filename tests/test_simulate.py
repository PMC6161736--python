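"""Generator correctness: selection model, error model, determinism, truth files."""

import json
import math

import numpy as np
import pytest
from scipy import stats

from ampliedit.reference import BarcodePair
from ampliedit.simulate import (
    SITE_ROLES,
    SimulationConfig,
    SimulationError,
    TruthRecord,
    emit_library,
    expected_pool_rates,
    random_sample_sheet,
    simulate_molecules,
    simulate_qpcr,
    simulate_sanger_peaks,
    simulate_site_counts,
)
from oracles import selection_pool_rates

BC = BarcodePair("ACACACAC", "GTGTGTGT")


def cfg(**kw):
    base = dict(depth_mean=500.0, depth_dispersion=50.0, error_rate=0.0, seed=1)
    base.update(kw)
    return SimulationConfig(**base)


def test_molecules_deterministic():
    c = cfg()
    a = simulate_molecules(c, 1000, seed=7)
    b = simulate_molecules(c, 1000, seed=7)
    assert (a[0] == b[0]).all() and (a[1] == b[1]).all()


def test_no_selection_keeps_rates():
    """With zero splicing penalties the spliced pool mirrors the pre-mRNA pool."""
    c = cfg(splice_penalty_qr=0.0, splice_penalty_intron=0.0,
            editing_marginals=(0.2, 0.6, 0.4))
    edits, spliced = simulate_molecules(c, 40_000, seed=3)
    pre = edits[:, 1].mean()
    spl = edits[spliced, 1].mean()
    # 4 sigma binomial tolerance
    assert abs(spl - pre) < 4 * math.sqrt(0.24 / spliced.sum())


def test_all_unedited_joint():
    joint = np.zeros((2, 2, 2))
    joint[0, 0, 0] = 1.0
    c = cfg(joint=joint)
    edits, _ = simulate_molecules(c, 5000, seed=5)
    assert not edits.any()


def test_selection_matches_enumeration_oracle():
    """lambda0=0, strong Q/R penalty: spliced-subset rate matches the closed
    form p*sigma(-l1) / (p*sigma(-l1) + (1-p)*sigma(0)) from brute-force
    enumeration over the 8 states."""
    c = cfg(splice_logit_base=0.0, splice_penalty_qr=4.0, splice_penalty_intron=0.0,
            editing_marginals=(0.0, 0.85, 0.0))
    edits, spliced = simulate_molecules(c, 200_000, seed=11)
    observed = edits[spliced, 1].mean()
    pre_o, mrna_o = selection_pool_rates(c.state_distribution(), 0.0, 4.0, 0.0)
    p, s_neg, s_zero = 0.85, 1 / (1 + math.exp(4.0)), 0.5
    closed = p * s_neg / (p * s_neg + (1 - p) * s_zero)
    assert mrna_o[1] == pytest.approx(closed, abs=1e-12)
    assert observed < 0.85
    assert observed == pytest.approx(closed, abs=4 * math.sqrt(0.25 / spliced.sum()))


def test_expected_pool_rates_agrees_with_oracle():
    c = cfg(editing_marginals=(0.3, 0.7, 0.5), splice_logit_base=1.0,
            splice_penalty_qr=2.0, splice_penalty_intron=1.5)
    got = expected_pool_rates(c)
    pre_o, mrna_o = selection_pool_rates(c.state_distribution(), 1.0, 2.0, 1.5)
    for i, role in enumerate(SITE_ROLES):
        assert got["pre_mrna"][role] == pytest.approx(pre_o[i], abs=1e-12)
        assert got["mrna"][role] == pytest.approx(mrna_o[i], abs=1e-12)


def test_selection_monotone_in_penalty():
    """Increasing the Q/R splicing penalty strictly decreases mRNA Q/R editing."""
    rates = []
    for l1 in (0.0, 1.0, 2.0, 3.0):
        c = cfg(splice_penalty_qr=l1, splice_penalty_intron=0.5)
        rates.append(expected_pool_rates(c)["mrna"]["Q/R"])
    assert all(a > b for a, b in zip(rates, rates[1:]))


def test_emit_error_free_unedited(flnb_ref):
    c = cfg(editing_marginals=(0.0, 0.0, 0.0), library_type="all")
    mols = simulate_molecules(c, 2000, seed=2)
    reads, truth = emit_library(mols, flnb_ref, BC, c, seed=2, sample_id="t")
    assert len(reads) == truth.depth > 0
    expected = BC.i5 + flnb_ref.sequence + BC.i7
    assert all(r.sequence == expected for r in reads)
    assert all(len(r.quality) == len(r.sequence) for r in reads)


def test_emit_g_fraction_within_binomial_interval(flnb_ref):
    """e=0, Q/R marginal 0.5, depth 10,000: G fraction at the Q/R offset lies
    in the 99% binomial interval around 0.5."""
    c = cfg(depth_mean=10_000.0, depth_dispersion=1e6,
            editing_marginals=(0.0, 0.5, 0.0), library_type="all")
    mols = simulate_molecules(c, 60_000, seed=9)
    reads, truth = emit_library(mols, flnb_ref, BC, c, seed=9)
    off = 8 + flnb_ref.site("Q/R")[0]
    g = sum(r.sequence[off] == "G" for r in reads)
    lo, hi = stats.binom.interval(0.99, len(reads), 0.5)
    assert lo <= g <= hi
    assert truth.sequenced_g_truth["Q/R"] == g  # e=0: reads carry truth exactly


def test_emit_deterministic(flnb_ref):
    c = cfg(error_rate=0.001)
    out = []
    for _ in range(2):
        mols = simulate_molecules(c, 3000, seed=4)
        reads, _ = emit_library(mols, flnb_ref, BC, c, seed=4)
        out.append("".join(r.fastq() for r in reads))
    assert out[0] == out[1]


def test_empty_pool_is_flagged_not_fatal(flnb_ref):
    joint = np.zeros((2, 2, 2))
    joint[0, 0, 0] = 1.0
    c = cfg(joint=joint, splice_logit_base=-50.0, library_type="mrna")
    mols = simulate_molecules(c, 500, seed=6)
    reads, truth = emit_library(mols, flnb_ref, BC, c, seed=6)
    assert reads == [] and truth.depth == 0


def test_error_floor_realism(flnb_ref):
    """e=0.001, editing 0: the G fraction at a site stays below 0.005 at
    depth >= 5,000 (binomial bound holds with large margin)."""
    c = cfg(depth_mean=5000.0, depth_dispersion=1e6, error_rate=0.001,
            editing_marginals=(0.0, 0.0, 0.0), library_type="all")
    mols = simulate_molecules(c, 30_000, seed=13)
    reads, _ = emit_library(mols, flnb_ref, BC, c, seed=13)
    off = 8 + flnb_ref.site("Q/R")[0]
    g_frac = sum(r.sequence[off] == "G" for r in reads) / len(reads)
    assert g_frac < 0.005


def test_truth_record_json_round_trip():
    t = TruthRecord("s1", 3, 1200, {"Q/R": 0.8}, {"Q/R": 0.5}, {"Q/R": 600}, 0.4)
    assert TruthRecord.from_json(t.to_json()) == t


def test_config_validation():
    with pytest.raises(SimulationError):
        SimulationConfig(error_rate=0.2)
    with pytest.raises(SimulationError):
        SimulationConfig(depth_mean=0)
    with pytest.raises(SimulationError):
        SimulationConfig(joint=np.ones((2, 2, 2)))


def test_config_yaml_round_trip(tmp_path):
    c = cfg(error_rate=0.001, editing_marginals=(0.1, 0.2, 0.3))
    p = tmp_path / "cfg.yaml"
    c.to_yaml(p)
    assert SimulationConfig.from_yaml(p) == c


@pytest.mark.parametrize("expr, expected_dct", [(1.0, 0.0), (0.25, 2.0)])
def test_qpcr_closed_form(expr, expected_dct):
    df = simulate_qpcr({"s": expr}, noise_sd=0.0, seed=0)
    dct = float(df.ct_target[0] - df.ct_reference[0])
    assert dct == pytest.approx(expected_dct, abs=1e-12)


def test_qpcr_noise_recovery(rng):
    """Mean recovered dCt over 50 noisy replicates is within 3 sd of truth."""
    truth_dct = -math.log2(0.4)
    dcts = []
    for i in range(50):
        df = simulate_qpcr({"s": 0.4}, noise_sd=0.2, seed=1000 + i)
        dcts.append(float(df.ct_target[0] - df.ct_reference[0]))
    se = 0.2 * math.sqrt(2)
    assert abs(np.mean(dcts) - truth_dct) < 3 * se / math.sqrt(50)


def test_qpcr_rejects_nonpositive_expression():
    with pytest.raises(SimulationError):
        simulate_qpcr({"s": 0.0})


@pytest.mark.parametrize("rate, expect_g", [(0.0, 0.0), (0.5, 0.5)])
def test_sanger_peaks_noise_free(rate, expect_g):
    a, g = simulate_sanger_peaks(rate, noise_sd=0.0, seed=0)
    assert g == pytest.approx(expect_g)
    assert a + g == pytest.approx(1.0)


def test_sanger_peaks_mean_ratio():
    ratios = []
    for i in range(200):
        a, g = simulate_sanger_peaks(0.3, noise_sd=0.05, seed=i)
        ratios.append(g / (a + g))
    assert abs(np.mean(ratios) - 0.3) < 0.02


def test_site_counts_error_model(rng):
    sc = simulate_site_counts(0.3, 20_000, 0.0, rng)
    assert sc.c == sc.t == sc.n == 0
    assert sc.a + sc.g == 20_000
    lo, hi = stats.binom.interval(0.999, 20_000, 0.3)
    assert lo <= sc.g <= hi


def test_random_sheet_separation():
    sheet = random_sample_sheet(40, seed=5, min_pair_distance=4)
    from ampliedit.reference import combined_distance

    pairs = [b for _, b in sheet]
    for i in range(len(pairs)):
        for j in range(i + 1, len(pairs)):
            assert combined_distance(pairs[i], pairs[j]) >= 4
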