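"""Random-effects meta-analysis of log response ratios.

Each ambient/warm paired comparison yields a log response ratio

    lnRR = ln(mean_warm / mean_ambient)

with the delta-method sampling variance

    v = sd_w^2 / (n_w * mean_w^2) + sd_a^2 / (n_a * mean_a^2),

the standard form for ratio-of-means effect sizes.  Comparisons are pooled
under a random-effects model: weights w_i = 1/(v_i + tau^2) where tau^2 is
the between-comparison variance (REML by default, DerSimonian-Laird as an
option), pooled mean sum(w*lnRR)/sum(w), SE sqrt(1/sum(w)), normal 95% CI.
Pooled log ratios are back-transformed to percentage change as
(exp(lnRR)-1)*100 for reporting.

Moderator (subgroup) analysis fits per-level means under a shared tau^2 and
tests their equality with the Wald-type QM statistic on a chi-square with
(levels - 1) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "EffectSize",
    "PooledResult",
    "ModeratorResult",
    "effect_size",
    "effects_from_pairs",
    "estimate_tau2",
    "pool",
    "moderator_analysis",
    "response_vs_warming",
    "bin_field_warming",
    "FIELD_WARMING_BINS",
]


@dataclass
class EffectSize:
    lnrr: float
    v: float  # within-comparison sampling variance
    n_profiles: int = 0
    moderators: dict = field(default_factory=dict)

    @property
    def degenerate(self) -> bool:
        return not (np.isfinite(self.lnrr) and self.v > 0)


@dataclass
class PooledResult:
    mean_lnrr: float
    se: float
    tau2: float
    ci95: tuple[float, float]
    k: int
    n_profiles: int = 0

    @property
    def percent_change(self) -> float:
        return 100.0 * (np.exp(self.mean_lnrr) - 1.0)

    @property
    def percent_ci95(self) -> tuple[float, float]:
        return tuple(100.0 * (np.exp(np.asarray(self.ci95)) - 1.0))


@dataclass
class ModeratorResult:
    moderator: str
    levels: dict  # level -> PooledResult
    qm: float  # NaN when only one level
    df: int
    p: float
    tau2: float


def effect_size(ambient, warm) -> EffectSize:
    """Log response ratio and delta-method variance from two group summaries.

    ``ambient`` and ``warm`` need ``mean``, ``sd`` and ``n`` attributes (e.g.
    :class:`soc_sft.grouping.GroupSummary`).  Both means must be positive and
    both groups must have n >= 2.
    """
    if ambient.mean <= 0 or warm.mean <= 0:
        raise ValueError("group means must be positive for a log response ratio")
    if ambient.n < 2 or warm.n < 2:
        raise ValueError("both groups need n >= 2")
    lnrr = float(np.log(warm.mean / ambient.mean))
    v = float(warm.sd ** 2 / (warm.n * warm.mean ** 2)
              + ambient.sd ** 2 / (ambient.n * ambient.mean ** 2))
    return EffectSize(lnrr=lnrr, v=v, n_profiles=ambient.n + warm.n)


def effects_from_pairs(pairs) -> tuple[list[EffectSize], list[dict]]:
    """Convert paired comparisons to effect sizes, skipping degenerate ones.

    Returns (effects, diagnostics); a comparison is skipped — with a recorded
    reason — when a mean is non-positive or both group variances are zero
    (zero sampling variance would receive infinite weight).
    """
    effects, skipped = [], []
    for p in pairs:
        try:
            es = effect_size(p.ambient, p.warm)
        except ValueError as err:
            skipped.append({"pair": p, "reason": str(err)})
            continue
        es.moderators = dict(p.moderators)
        if es.degenerate:
            skipped.append({"pair": p, "reason": "zero sampling variance"})
            continue
        effects.append(es)
    return effects, skipped


def _arrays(effects):
    y = np.array([e.lnrr for e in effects], dtype=float)
    v = np.array([e.v for e in effects], dtype=float)
    return y, v


def _reml_tau2(y, v, X=None) -> float:
    """REML estimate of tau^2 for y ~ X b + u, u ~ N(0, tau^2), given v.

    X defaults to an intercept column.  The restricted log-likelihood is
    profiled over the fixed effects and maximized over tau^2 >= 0.
    """
    if X is None:
        X = np.ones((len(y), 1))

    def neg_restricted_ll(tau2):
        w = 1.0 / (v + tau2)
        XtWX = X.T @ (X * w[:, None])
        beta = np.linalg.solve(XtWX, X.T @ (w * y))
        resid = y - X @ beta
        sign, logdet = np.linalg.slogdet(XtWX)
        return 0.5 * (np.sum(np.log(v + tau2)) + logdet + np.sum(w * resid ** 2))

    upper = max(10.0 * float(np.var(y)), 10.0 * float(v.max()), 1e-3)
    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(0.0, upper),
                                   method="bounded", options={"xatol": 1e-10})
    return float(res.x)


def _dl_tau2(y, v) -> float:
    """DerSimonian-Laird moment estimator of tau^2."""
    w = 1.0 / v
    ybar = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (y - ybar) ** 2)
    denom = np.sum(w) - np.sum(w ** 2) / np.sum(w)
    return float(max(0.0, (q - (len(y) - 1)) / denom)) if denom > 0 else 0.0


def estimate_tau2(effects, method: str = "reml") -> float:
    """Between-comparison variance tau^2 (>= 0)."""
    if len(effects) < 2:
        import warnings
        warnings.warn("fewer than 2 effects; tau^2 set to 0", stacklevel=2)
        return 0.0
    y, v = _arrays(effects)
    if method == "reml":
        return _reml_tau2(y, v)
    if method == "dl":
        return _dl_tau2(y, v)
    raise ValueError(f"unknown tau^2 method {method!r}")


def pool(effects, tau2: float | None = None, method: str = "reml") -> PooledResult:
    """Inverse-variance weighted random-effects pooled mean with 95% CI."""
    if len(effects) == 0:
        raise ValueError("no effects to pool")
    if tau2 is None:
        tau2 = estimate_tau2(effects, method) if len(effects) > 1 else 0.0
    y, v = _arrays(effects)
    w = 1.0 / (v + tau2)
    mean = float(np.sum(w * y) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    return PooledResult(
        mean_lnrr=mean, se=se, tau2=float(tau2),
        ci95=(mean - 1.96 * se, mean + 1.96 * se), k=len(effects),
        n_profiles=int(sum(e.n_profiles for e in effects)),
    )


def moderator_analysis(effects, moderator_name: str, method: str = "reml") -> ModeratorResult:
    """Subgroup means under a shared tau^2 plus the QM equality test."""
    levels = {}
    for e in effects:
        levels.setdefault(e.moderators.get(moderator_name), []).append(e)
    if not levels:
        raise ValueError("no effects")

    y, v = _arrays(effects)
    names = sorted(levels, key=str)
    if len(names) > 1 and len(effects) > len(names):
        X = np.column_stack([
            [1.0 if e.moderators.get(moderator_name) == name else 0.0 for e in effects]
            for name in names])
        tau2 = _reml_tau2(y, v, X) if method == "reml" else _dl_tau2(y, v)
    else:
        tau2 = 0.0

    per_level = {name: pool(levels[name], tau2=tau2) for name in names}
    if len(names) > 1:
        means = np.array([per_level[n].mean_lnrr for n in names])
        inv_se2 = np.array([1.0 / per_level[n].se ** 2 for n in names])
        grand = np.sum(inv_se2 * means) / np.sum(inv_se2)
        qm = float(np.sum(inv_se2 * (means - grand) ** 2))
        df = len(names) - 1
        p = float(stats.chi2.sf(qm, df))
    else:
        qm, df, p = float("nan"), 0, float("nan")
    return ModeratorResult(moderator_name, per_level, qm, df, p, tau2)


def response_vs_warming(pooled_by_level: dict) -> dict:
    """OLS of pooled percentage change on warming level (degC).

    ``pooled_by_level`` maps warming level -> PooledResult.  Returns slope
    (% per degC), intercept, r2 and the slope's p-value.
    """
    if len(pooled_by_level) < 2:
        raise ValueError("need at least two warming levels")
    dts = np.array(sorted(pooled_by_level), dtype=float)
    pct = np.array([pooled_by_level[d].percent_change for d in sorted(pooled_by_level)])
    fit = stats.linregress(dts, pct)
    return {"slope": float(fit.slope), "intercept": float(fit.intercept),
            "r2": float(fit.rvalue ** 2), "p": float(fit.pvalue)}


FIELD_WARMING_BINS = ("<1", "1-2", "2-3", "3-4", "4-5", ">5")


def _bin_delta_t(dt: float) -> str:
    """Half-open warming bins: [0,1), [1,2), ..., [5, inf)."""
    if dt < 0:
        raise ValueError("warming magnitude must be >= 0")
    if dt < 1:
        return "<1"
    if dt >= 5:
        return ">5"
    lo = int(dt)
    return f"{lo}-{lo + 1}"


@dataclass
class _Summary:
    mean: float
    sd: float
    n: int


def bin_field_warming(observations: pd.DataFrame, method: str = "reml") -> dict:
    """Meta-analysis of field warming experiments by warming bin and ecosystem.

    ``observations`` needs columns delta_t, ambient_mean, ambient_sd,
    ambient_n, warm_mean, warm_sd, warm_n and optionally ecosystem.  Returns
    {"by_bin": ModeratorResult, "by_ecosystem": ModeratorResult | None};
    empty bins simply do not appear (and contribute no QM degrees of freedom).
    """
    effects = []
    for _, row in observations.iterrows():
        es = effect_size(
            _Summary(row["ambient_mean"], row["ambient_sd"], int(row["ambient_n"])),
            _Summary(row["warm_mean"], row["warm_sd"], int(row["warm_n"])))
        if es.degenerate:
            continue
        es.moderators = {"warming_bin": _bin_delta_t(float(row["delta_t"]))}
        if "ecosystem" in observations.columns:
            es.moderators["ecosystem"] = row["ecosystem"]
        effects.append(es)
    if not effects:
        raise ValueError("no usable observations")
    out = {"by_bin": moderator_analysis(effects, "warming_bin", method)}
    out["by_ecosystem"] = (moderator_analysis(effects, "ecosystem", method)
                           if "ecosystem" in observations.columns else None)
    return out
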