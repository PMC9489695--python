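"""Effect sizes, tau^2, pooling, moderators, warming-level regression.

Pooling is checked against an independent brute-force implementation of the
inverse-variance weighting written directly from the weighted-mean formulas,
and against statsmodels' meta-analysis routines where they overlap.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from soc_sft.grouping import GroupKey, GroupSummary
from soc_sft.meta import (EffectSize, PooledResult, bin_field_warming, effect_size,
                          effects_from_pairs, estimate_tau2, moderator_analysis, pool,
                          response_vs_warming)
from soc_sft.q10 import steady_state_response

KEY = GroupKey("plains", "mollisols", "summer", 9)


def _summary(mean, sd, n):
    return GroupSummary(KEY, 0, n, mean, sd, 500.0, 5.0)


def _effects(lnrrs, vs):
    return [EffectSize(l, v, n_profiles=4) for l, v in zip(lnrrs, vs)]


# --- independent brute-force oracle -----------------------------------------

def brute_pool(lnrrs, vs, tau2):
    w = [1.0 / (v + tau2) for v in vs]
    mean = sum(l * wi for l, wi in zip(lnrrs, w)) / sum(w)
    se = (1.0 / sum(w)) ** 0.5
    return mean, se


def brute_dl_tau2(lnrrs, vs):
    w = [1.0 / v for v in vs]
    ybar = sum(l * wi for l, wi in zip(lnrrs, w)) / sum(w)
    q = sum(wi * (l - ybar) ** 2 for l, wi in zip(lnrrs, w))
    c = sum(w) - sum(wi ** 2 for wi in w) / sum(w)
    return max(0.0, (q - (len(vs) - 1)) / c)


# ---------------------------------------------------------------------------

def test_effect_size_examples():
    assert effect_size(_summary(100, 10, 5), _summary(100, 10, 5)).lnrr == 0.0
    es = effect_size(_summary(100, 10, 5), _summary(50, 5, 5))
    assert es.lnrr == pytest.approx(np.log(0.5), abs=1e-4)
    # delta-method variance
    assert es.v == pytest.approx(25 / (5 * 50**2) + 100 / (5 * 100**2))


def test_effect_size_guards():
    with pytest.raises(ValueError, match="positive"):
        effect_size(_summary(0.0, 1, 5), _summary(10, 1, 5))
    with pytest.raises(ValueError, match="n >= 2"):
        effect_size(_summary(10, 1, 1), _summary(10, 1, 5))
    assert effect_size(_summary(10, 0, 5), _summary(20, 0, 5)).degenerate


def test_tau2_identical_effects_zero():
    effects = _effects([0.2, 0.2, 0.2], [0.01, 0.01, 0.01])
    assert estimate_tau2(effects, "dl") == 0.0
    assert estimate_tau2(effects, "reml") == pytest.approx(0.0, abs=1e-6)


def test_dl_tau2_matches_hand_formula():
    lnrrs, vs = [0.1, -0.3, 0.25], [0.02, 0.05, 0.04]
    assert estimate_tau2(_effects(lnrrs, vs), "dl") == pytest.approx(
        brute_dl_tau2(lnrrs, vs), rel=1e-12)
    # scaling all v scales the DL estimate predictably on the same toy
    for c in (0.5, 2.0, 10.0):
        scaled = [v * c for v in vs]
        assert estimate_tau2(_effects(lnrrs, scaled), "dl") == pytest.approx(
            brute_dl_tau2(lnrrs, scaled), rel=1e-12)


def test_dl_matches_statsmodels():
    sm = pytest.importorskip("statsmodels.stats.meta_analysis")
    lnrrs = [0.12, -0.28, 0.33, -0.05, 0.19]
    vs = [0.02, 0.06, 0.03, 0.08, 0.045]
    res = sm.combine_effects(np.array(lnrrs), np.array(vs), method_re="dl")
    tau2 = estimate_tau2(_effects(lnrrs, vs), "dl")
    assert tau2 == pytest.approx(res.tau2, rel=1e-8)
    pooled = pool(_effects(lnrrs, vs), tau2=tau2)
    assert pooled.mean_lnrr == pytest.approx(res.mean_effect_re, rel=1e-8)


def test_reml_tau2_reasonable():
    # strong heterogeneity: REML tau2 should be near the spread of true means
    rng = np.random.default_rng(0)
    true = rng.normal(0, 0.3, 200)
    vs = np.full(200, 0.01)
    effects = _effects(true + rng.normal(0, 0.1, 200), vs)
    tau2 = estimate_tau2(effects, "reml")
    assert 0.05 < tau2 < 0.2  # ~0.09 + 0.01 measurement part


def test_pool_examples_and_oracle():
    single = _effects([0.3], [0.02])
    assert pool(single).mean_lnrr == pytest.approx(0.3)
    equal = _effects([0.1, 0.2, 0.3], [0.05, 0.05, 0.05])
    assert pool(equal, tau2=0.0).mean_lnrr == pytest.approx(0.2)
    lnrrs = [0.12, -0.28, 0.33, -0.05, 0.19]
    vs = [0.02, 0.06, 0.03, 0.08, 0.045]
    for tau2 in (0.0, 0.03):
        mean, se = brute_pool(lnrrs, vs, tau2)
        got = pool(_effects(lnrrs, vs), tau2=tau2)
        assert got.mean_lnrr == pytest.approx(mean, abs=1e-12)
        assert got.se == pytest.approx(se, abs=1e-12)
        assert got.ci95 == pytest.approx((mean - 1.96 * se, mean + 1.96 * se))


@settings(deadline=None, max_examples=60)
@given(st.lists(st.tuples(st.floats(-1, 1), st.floats(0.001, 0.5)), min_size=1, max_size=12))
def test_pooled_mean_within_input_range(pairs):
    effects = _effects([l for l, _ in pairs], [v for _, v in pairs])
    pooled = pool(effects)
    lnrrs = [l for l, _ in pairs]
    assert min(lnrrs) - 1e-9 <= pooled.mean_lnrr <= max(lnrrs) + 1e-9
    # back-transform is monotone and bounded below by -100%
    assert pooled.percent_change > -100.0


def test_backtransform_monotone():
    results = [pool(_effects([l], [0.01])) for l in (-0.3, -0.1, 0.2)]
    pcts = [r.percent_change for r in results]
    assert pcts == sorted(pcts)


def test_moderator_separation_and_single_level():
    rng = np.random.default_rng(1)
    effects = []
    for level, mu in (("a", -0.5), ("b", 0.5)):
        for _ in range(15):
            e = EffectSize(mu + rng.normal(0, 0.05), 0.01)
            e.moderators = {"biome": level}
            effects.append(e)
    res = moderator_analysis(effects, "biome")
    assert res.qm > 6.63 and res.p < 0.01
    assert res.levels["a"].mean_lnrr < res.levels["b"].mean_lnrr
    # all-equal means -> QM ~ 0
    flat = []
    for level in ("a", "b"):
        for _ in range(10):
            e = EffectSize(0.2, 0.01)
            e.moderators = {"biome": level}
            flat.append(e)
    assert moderator_analysis(flat, "biome").qm == pytest.approx(0.0, abs=1e-10)
    # single level: per-level output equals pool(), QM undefined
    solo = moderator_analysis([e for e in effects if e.moderators["biome"] == "a"], "biome")
    assert np.isnan(solo.qm) and solo.df == 0
    assert solo.levels["a"].mean_lnrr == pytest.approx(
        pool([e for e in effects if e.moderators["biome"] == "a"]).mean_lnrr, abs=1e-6)


def test_response_vs_warming_exact_line_and_constant():
    def pooled(pct):
        lnrr = np.log(1 + pct / 100)
        return PooledResult(lnrr, 0.01, 0.0, (lnrr, lnrr), 5)

    exact = {d: pooled(-2.0 - 3.0 * d) for d in range(1, 6)}
    fit = response_vs_warming(exact)
    assert fit["r2"] == pytest.approx(1.0)
    assert fit["slope"] == pytest.approx(-3.0)
    flat = {d: pooled(-4.0) for d in range(1, 6)}
    assert response_vs_warming(flat)["slope"] == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        response_vs_warming({1: pooled(-2.0)})


def test_response_vs_warming_q10_curve_slope():
    # independent OLS oracle on the closed-form steady-state curve at Q10=1.7
    dts = np.arange(1, 6, dtype=float)
    pct = steady_state_response(1.7, dts)
    slope_oracle = np.polyfit(dts, pct, 1)[0]
    pooled = {d: PooledResult(np.log(1 + p / 100), 0.01, 0.0, (0, 0), 5)
              for d, p in zip(dts, pct)}
    assert response_vs_warming(pooled)["slope"] == pytest.approx(slope_oracle, rel=1e-6)
    assert slope_oracle == pytest.approx(-4.53, abs=0.01)


def test_field_warming_bins():
    obs = pd.DataFrame({
        "delta_t": [0.1, 2.0, 2.9, 5.0, 7.0],
        "ambient_mean": [100.0] * 5, "ambient_sd": [10.0] * 5, "ambient_n": [6] * 5,
        "warm_mean": [98.0, 95.0, 96.0, 90.0, 88.0],
        "warm_sd": [10.0] * 5, "warm_n": [6] * 5,
        "ecosystem": ["tundra", "forest", "forest", "grassland", "grassland"],
    })
    res = bin_field_warming(obs)
    by_bin = res["by_bin"]
    # half-open bins: 0.1 -> "<1", 2.0 and 2.9 -> "2-3", 5.0 and 7.0 -> ">5"
    assert set(by_bin.levels) == {"<1", "2-3", ">5"}
    assert by_bin.levels["2-3"].k == 2
    assert by_bin.df == 2  # empty bins contribute no degrees of freedom
    assert set(res["by_ecosystem"].levels) == {"tundra", "forest", "grassland"}


def test_effects_from_pairs_skips_degenerate():
    class P:
        def __init__(self, a, w):
            self.ambient, self.warm, self.moderators = a, w, {}

    good = P(_summary(100, 10, 5), _summary(90, 9, 5))
    bad_mean = P(_summary(-1, 10, 5), _summary(90, 9, 5))
    zero_var = P(_summary(100, 0, 5), _summary(90, 0, 5))
    effects, skipped = effects_from_pairs([good, bad_mean, zero_var])
    assert len(effects) == 1 and len(skipped) == 2
    reasons = {s["reason"] for s in skipped}
    assert any("positive" in r for r in reasons)
    assert any("variance" in r for r in reasons)
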