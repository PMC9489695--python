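"""End-to-end convenience wrappers: impute -> harmonize -> pair -> pool.

These chain the stage modules with their defaults so that a profile table
plus an environment table goes to depth-resolved pooled warming responses in
one call.  Each stage remains available separately for custom workflows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import grouping, meta, profiles as prof
from .q10 import Q10Scenario, fit_q10

__all__ = ["prepare_profiles", "estimate_warming_responses", "effects_table", "fit_layer_q10"]


def prepare_profiles(profile_list, environments, seed: int = 0,
                     lambda_smooth=None, impute: bool = True) -> pd.DataFrame:
    """Impute missing BD/gravel where needed, then harmonize to standard depths."""
    filled = profile_list
    if impute:
        for target in ("bd", "gravel"):
            has_missing = any(getattr(l, target) is None
                              for p in filled for l in p.layers)
            if has_missing:
                filled, _ = prof.impute_missing(filled, target, seed=seed,
                                                environments=environments)
    kwargs = {} if lambda_smooth is None else {"lambda_smooth": lambda_smooth}
    return prof.harmonize_profiles(filled, **kwargs)


def estimate_warming_responses(profile_list, environments, layers=prof.LAYER_LABELS,
                               warming_levels=(1, 2, 3, 4, 5), response="soc_s",
                               seed: int = 0, tau2_method="reml",
                               impute: bool = True, lambda_smooth=None,
                               **pair_kwargs) -> pd.DataFrame:
    """Pooled percentage SOC response per (layer, warming level).

    Returns a frame with columns layer, warming_level, percent_change,
    ci_low, ci_high, k (number of paired comparisons), n_profiles and tau2.
    Layer/level combinations yielding no pairs are omitted.
    """
    harmonized = prepare_profiles(profile_list, environments, seed=seed,
                                  lambda_smooth=lambda_smooth, impute=impute)
    env_frame = grouping.environments_frame(environments)
    rows = []
    for layer in layers:
        for dt in warming_levels:
            pairs = grouping.build_pairs(env_frame, harmonized, layer, dt,
                                         response=response, **pair_kwargs)
            effects, _ = meta.effects_from_pairs(pairs)
            if not effects:
                continue
            pooled = meta.pool(effects, method=tau2_method)
            lo, hi = pooled.percent_ci95
            rows.append({"layer": layer, "warming_level": dt,
                         "percent_change": pooled.percent_change,
                         "ci_low": lo, "ci_high": hi, "k": pooled.k,
                         "n_profiles": pooled.n_profiles, "tau2": pooled.tau2})
    return pd.DataFrame(rows)


def effects_table(pairs, tau2_method="reml") -> pd.DataFrame:
    """Effect sizes with meta-analytic weights and moderators, one row each.

    The outcome column ``percent_change`` is the back-transformed effect and
    ``weight`` is 1/(v + tau^2) with tau^2 estimated across the given pairs —
    the table the meta-forest stage trains on.
    """
    effects, _ = meta.effects_from_pairs(pairs)
    if not effects:
        return pd.DataFrame()
    tau2 = meta.estimate_tau2(effects, tau2_method)
    rows = []
    for e in effects:
        rows.append({"lnrr": e.lnrr, "v": e.v,
                     "percent_change": 100.0 * (np.exp(e.lnrr) - 1.0),
                     "weight": 1.0 / (e.v + tau2), **e.moderators})
    return pd.DataFrame(rows)


def fit_layer_q10(responses_by_layer: dict, input_rate_per_degree: float = 0.0) -> pd.DataFrame:
    """Fit Q10 per layer from {layer: [(delta_t, percent), ...]} responses."""
    scenario = Q10Scenario(input_rate_per_degree)
    rows = []
    for layer, responses in responses_by_layer.items():
        fit = fit_q10(responses, scenario, layer=layer)
        rows.append({"layer": layer, "input_rate_per_degree": input_rate_per_degree,
                     "q10": fit.q10, "sse": fit.sse})
    return pd.DataFrame(rows)
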