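"""Model fits checked against independent oracles and known identities."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lexidrift.errors import DegenerateInputError
from lexidrift.inference import (
    fit_binomial_groups,
    fit_gamma_ratio_gee,
    fit_gaussian_groups,
    tukey_adjust,
)


def test_gaussian_omnibus_matches_f_oneway():
    rng = np.random.default_rng(0)
    groups = pd.Series(np.repeat(["a", "b", "c"], 30))
    y = pd.Series(rng.normal(0, 1, 90) + (groups == "b") * 0.8)
    summary = fit_gaussian_groups(y, groups)
    oracle = stats.f_oneway(y[groups == "a"], y[groups == "b"],
                            y[groups == "c"])
    assert summary.statistic == pytest.approx(oracle.statistic, rel=1e-10)
    assert summary.p_value == pytest.approx(oracle.pvalue, rel=1e-10)
    assert summary.df == (2.0, 87.0)
    assert len(summary.contrasts) == 3


def test_gaussian_constant_response_is_null():
    groups = pd.Series(["a"] * 5 + ["b"] * 5)
    summary = fit_gaussian_groups(pd.Series([2.0] * 10), groups)
    assert summary.statistic == 0.0
    assert summary.p_value == 1.0


def test_gaussian_needs_enough_observations():
    with pytest.raises(DegenerateInputError):
        fit_gaussian_groups(pd.Series([1.0, 2.0]), pd.Series(["a", "b"]))


def test_binomial_two_group_lr_matches_hand_computation():
    # two cells per group, well-separated proportions
    successes = pd.Series([30, 28, 5, 7])
    totals = pd.Series([100, 100, 100, 100])
    groups = pd.Series(["a", "a", "b", "b"])
    summary = fit_binomial_groups(successes, totals, groups)

    def loglik(s, t, p):
        return float(np.sum(s * np.log(p) + (t - s) * np.log(1 - p)))

    s, t = successes.to_numpy(), totals.to_numpy()
    p_full = np.array([58 / 200, 58 / 200, 12 / 200, 12 / 200])
    p_null = np.full(4, 70 / 400)
    lr = 2 * (loglik(s, t, p_full) - loglik(s, t, p_null))
    assert summary.statistic == pytest.approx(lr, rel=1e-8)
    assert summary.df == (1.0,)
    assert summary.p_value == pytest.approx(stats.chi2.sf(lr, 1), rel=1e-8)
    # response-scale contrast recovers the proportion difference
    (c,) = summary.contrasts
    assert c.estimate_response == pytest.approx(58 / 200 - 12 / 200, abs=1e-8)


def test_binomial_equal_groups_is_well_calibrated():
    """Two equal-proportion groups: |p_a - p_b| within 2 SE in >= 95% of
    seeded replicates (binomial sampling oracle)."""
    rng = np.random.default_rng(12)
    n, p_true = 100, 0.3  # per cell; two cells per group
    inside = 0
    n_rep = 100
    groups = pd.Series(["a", "a", "b", "b"])
    for _ in range(n_rep):
        s = rng.binomial(n, p_true, size=4)
        summary = fit_binomial_groups(
            pd.Series(s), pd.Series([n] * 4), groups
        )
        (c,) = summary.contrasts
        pa, pb = (s[0] + s[1]) / (2 * n), (s[2] + s[3]) / (2 * n)
        se_resp = np.sqrt(pa * (1 - pa) / (2 * n) + pb * (1 - pb) / (2 * n))
        inside += abs(c.estimate_response) <= 2 * se_resp + 1e-12
    assert inside / n_rep >= 0.95


def test_binomial_all_zero_successes_is_null():
    summary = fit_binomial_groups(
        pd.Series([0, 0]), pd.Series([50, 50]), pd.Series(["a", "b"])
    )
    assert summary.statistic == 0.0
    assert summary.p_value == 1.0


def test_tukey_two_groups_reduces_to_z_test():
    t = np.array([1.5, 2.2])
    adj = tukey_adjust(t, n_levels=2, df=1e7)
    two_sided = 2 * stats.norm.sf(np.abs(t))
    assert adj == pytest.approx(two_sided, rel=1e-4)


def test_tukey_is_more_conservative_with_more_groups():
    t = np.array([2.0])
    p2 = tukey_adjust(t, n_levels=2, df=1e7)[0]
    p4 = tukey_adjust(t, n_levels=4, df=1e7)[0]
    assert p4 > p2


def _ratio_frame(seed, effect=0.0, n_cues=24, per_cell=4):
    """Gamma ratios around 1 with an optional pandemic x covid-only bump."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_cues):
        ct = ["control", "pandemic"][i % 2]
        for nt in ("shared", "covid-only"):
            mu = 1.0 + effect * (ct == "pandemic") * (nt == "covid-only")
            shape = 30.0
            vals = rng.gamma(shape, mu / shape, per_cell)
            for v in vals:
                rows.append({"cue": f"c{i}", "cue_type": ct,
                             "category": nt, "ratio": v})
    return pd.DataFrame(rows)


def test_gamma_gee_detects_interaction():
    df = _ratio_frame(seed=0, effect=0.6)
    summary, by_neighbor = fit_gamma_ratio_gee(
        df["ratio"], df["cue_type"], df["category"], df["cue"]
    )
    assert summary.df == (1.0,)  # (2-1) x (2-1) interaction df
    assert summary.p_value < 0.01
    # within covid-only neighbors, pandemic differs from control
    (c,) = by_neighbor["covid-only"]
    assert c.p_adjusted < 0.05
    # response-scale means are 1/eta: pandemic mean larger in covid-only
    assert c.estimate_response != 0


def test_gamma_gee_null_interaction_not_significant():
    df = _ratio_frame(seed=1, effect=0.0)
    summary, _ = fit_gamma_ratio_gee(
        df["ratio"], df["cue_type"], df["category"], df["cue"]
    )
    assert summary.p_value > 0.05


def test_gamma_gee_rejects_nonpositive_ratios():
    df = _ratio_frame(seed=2)
    df.loc[0, "ratio"] = 0.0
    with pytest.raises(DegenerateInputError):
        fit_gamma_ratio_gee(df["ratio"], df["cue_type"], df["category"],
                            df["cue"])


def test_gamma_gee_constant_ratios_is_null():
    df = _ratio_frame(seed=3)
    df["ratio"] = 1.0
    summary, by_neighbor = fit_gamma_ratio_gee(
        df["ratio"], df["cue_type"], df["category"], df["cue"]
    )
    assert summary.statistic == 0.0
    assert summary.p_value == 1.0
    assert by_neighbor == {}
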