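"""One-pool steady-state SOC model with Q10 temperature sensitivity.

The model is dC/dt = I - k*C with carbon input I and first-order decay k, so
the steady state is C = I/k.  Warming by dT multiplies the decay rate by
Q10^(dT/10) (Q10 is the factor per 10 degC) and may change inputs by a
factor I_w/I, giving the steady-state percentage response

    R = 100 * (I_w/I * Q10^(-dT/10) - 1).

Input-change scenarios compound: a rate r per degC gives I_w/I = (1+r)^dT.
Under that convention the fitted Q10 obeys the exact identity
q10(r) = q10(0) * (1+r)^10, because (1+r)^dT * Q10^(-dT/10) =
(Q10/(1+r)^10)^(-dT/10).

Fitting inverts the response curve: given estimated percentage responses at
several warming levels, the Q10 minimizing the sum of squared deviations of
the modelled from the estimated responses is found by bounded 1-D
minimization on Q10 in [1, 10].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["Q10Scenario", "Q10Fit", "steady_state_response", "input_ratio", "fit_q10",
           "Q10_BOUNDS"]

Q10_BOUNDS = (1.0, 10.0)


@dataclass(frozen=True)
class Q10Scenario:
    """Carbon-input change under warming: fractional rate per degC, compounded."""

    input_rate_per_degree: float = 0.0

    def __post_init__(self):
        if self.input_rate_per_degree < -1:
            raise ValueError("input rate per degree must be >= -1")


@dataclass
class Q10Fit:
    layer: str | None
    scenario: Q10Scenario
    q10: float
    sse: float
    responses_used: tuple  # ((delta_t, percent), ...)


def steady_state_response(q10, delta_t, input_ratio=1.0):
    """Percentage steady-state SOC response to ``delta_t`` warming.

    Vectorized over ``delta_t``.  Negative values are losses.
    """
    q10 = float(q10)
    if q10 <= 0:
        raise ValueError("q10 must be positive")
    delta_t = np.asarray(delta_t, dtype=float)
    if np.any(delta_t < 0):
        raise ValueError("delta_t must be >= 0")
    out = 100.0 * (np.asarray(input_ratio, dtype=float)
                   * np.exp(-0.1 * delta_t * np.log(q10)) - 1.0)
    return float(out) if out.ndim == 0 else out


def input_ratio(scenario: Q10Scenario, delta_t):
    """Warm/ambient carbon-input ratio (1+r)^dT for the scenario."""
    delta_t = np.asarray(delta_t, dtype=float)
    out = (1.0 + scenario.input_rate_per_degree) ** delta_t
    return float(out) if out.ndim == 0 else out


def fit_q10(responses, scenario: Q10Scenario = Q10Scenario(), layer=None,
            weights=None, xatol: float = 1e-8) -> Q10Fit:
    """Least-squares Q10 from (delta_t, percent response) pairs.

    ``responses`` is a sequence of (warming level degC, percentage response)
    pairs; optional ``weights`` (same length) turn the objective into a
    weighted sum of squares.  Deterministic bounded minimization on
    Q10 in [1, 10].
    """
    responses = tuple((float(d), float(r)) for d, r in responses)
    if len(responses) < 2:
        raise ValueError("need at least two response points")
    dts = np.array([d for d, _ in responses])
    obs = np.array([r for _, r in responses])
    wts = np.ones_like(obs) if weights is None else np.asarray(weights, dtype=float)
    if wts.shape != obs.shape or np.any(wts < 0):
        raise ValueError("weights must be non-negative, one per response")
    ir = input_ratio(scenario, dts)

    def sse(q10):
        return float(np.sum(wts * (steady_state_response(q10, dts, ir) - obs) ** 2))

    res = optimize.minimize_scalar(sse, bounds=Q10_BOUNDS, method="bounded",
                                   options={"xatol": xatol})
    if not res.success:
        raise RuntimeError(f"Q10 fit did not converge: {res.message}")
    return Q10Fit(layer=layer, scenario=scenario, q10=float(res.x),
                  sse=float(res.fun), responses_used=responses)
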