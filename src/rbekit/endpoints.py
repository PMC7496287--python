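"""Experimental RBE at iso-survival levels and fixed proton doses.

The RBE at an endpoint is the ratio of the reference (x-ray) dose to the
proton dose producing the same surviving fraction.  For a fixed proton
dose Dp the closed form in terms of the LQ parameters is

    RBE(Dp) = [sqrt(α_x² + 4 β_x Dp (α_p + β_p Dp)) − α_x] / (2 β_x Dp)

which is exactly the x-ray/proton equal-effect dose ratio.  Standard
errors are obtained by the delta method over (α_x, β_x, α_p, β_p),
treating the x-ray and proton fits as independent experiments but using
each fit's internal parameter covariance.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .types import (
    BeamCondition,
    EndpointSpec,
    LQParameters,
    Radiation,
    RBEEstimate,
    RBESource,
    ValidationError,
)

log = logging.getLogger(__name__)


def dose_for_survival(lq: LQParameters, survival: float) -> float:
    """Dose (Gy) at which the LQ curve reaches the given surviving fraction.

    Solves βD² + αD + ln S = 0 for the unique positive root (or the linear
    case D = −ln S / α when β = 0).
    """
    if not 0 < survival <= 1:
        raise ValidationError(f"survival must lie in (0, 1], got {survival}")
    if survival == 1.0:
        return 0.0
    if lq.alpha == 0 and lq.beta == 0:
        raise ValidationError("alpha = beta = 0: no dose produces this effect")
    effect = -math.log(survival)
    # numerically stable positive root of βD² + αD − effect = 0 (exact in
    # the β → 0 limit, avoiding the 0/0 of the textbook quadratic formula)
    return 2 * effect / (lq.alpha + math.sqrt(lq.alpha**2 + 4 * lq.beta * effect))


def rbe_fixed_dose(
    alpha_x: float, beta_x: float, alpha_p: float, beta_p: float, dp: float
) -> float:
    """Closed-form RBE at a fixed proton dose from the four LQ parameters."""
    if dp <= 0:
        raise ValidationError(f"proton dose must be > 0, got {dp}")
    if beta_x == 0:
        # Limit of the closed form as β_x → 0: the x-ray curve is purely
        # linear and the equal-effect ratio reduces to effect/ (α_x Dp).
        log.info("beta_x = 0: using the linear-reference limit formula")
        return (alpha_p + beta_p * dp) / alpha_x
    disc = alpha_x**2 + 4 * beta_x * dp * (alpha_p + beta_p * dp)
    return (math.sqrt(disc) - alpha_x) / (2 * beta_x * dp)


def _delta_se_two_fits(fn, lq_x: LQParameters, lq_p: LQParameters) -> float:
    """Delta-method SE of fn(α_x, β_x, α_p, β_p) with two independent fits.

    Gradients by central differences; each fit contributes g' C g with its
    own 2x2 parameter covariance.
    """
    theta = np.array([lq_x.alpha, lq_x.beta, lq_p.alpha, lq_p.beta], dtype=float)
    grad = np.zeros(4)
    for i in range(4):
        h = 1e-6 * max(abs(theta[i]), 1e-3)
        up, dn = theta.copy(), theta.copy()
        up[i] += h
        dn[i] -= h
        grad[i] = (fn(*up) - fn(*dn)) / (2 * h)
    var = grad[:2] @ lq_x.covariance @ grad[:2] + grad[2:] @ lq_p.covariance @ grad[2:]
    return float(np.sqrt(max(var, 0.0)))


def rbe_at_dose(
    lq_x: LQParameters,
    lq_p: LQParameters,
    dp: float,
    condition: BeamCondition | None = None,
    cell_line: str = "",
) -> RBEEstimate:
    """Experimental RBE at a fixed proton dose Dp with propagated SE."""

    def f(ax, bx, ap, bp):
        return rbe_fixed_dose(ax, bx, ap, bp, dp)

    value = f(lq_x.alpha, lq_x.beta, lq_p.alpha, lq_p.beta)
    se = _delta_se_two_fits(f, lq_x, lq_p)
    return RBEEstimate(
        value=value,
        se=se,
        endpoint=EndpointSpec.at_dose(dp),
        condition=condition or BeamCondition(Radiation.PROTON),
        source=RBESource.EXPERIMENTAL,
        cell_line=cell_line,
    )


def rbe_at_survival(
    lq_x: LQParameters,
    lq_p: LQParameters,
    survival: float,
    condition: BeamCondition | None = None,
    cell_line: str = "",
) -> RBEEstimate:
    """Experimental RBE at an iso-survival level with propagated SE."""

    def f(ax, bx, ap, bp):
        dx = dose_for_survival(LQParameters(alpha=ax, beta=bx), survival)
        dp = dose_for_survival(LQParameters(alpha=ap, beta=bp), survival)
        return dx / dp

    value = f(lq_x.alpha, lq_x.beta, lq_p.alpha, lq_p.beta)
    se = _delta_se_two_fits(f, lq_x, lq_p)
    return RBEEstimate(
        value=value,
        se=se,
        endpoint=EndpointSpec.at_survival(survival),
        condition=condition or BeamCondition(Radiation.PROTON),
        source=RBESource.EXPERIMENTAL,
        cell_line=cell_line,
    )


def rbe_at_endpoint(
    lq_x: LQParameters,
    lq_p: LQParameters,
    endpoint: EndpointSpec,
    condition: BeamCondition | None = None,
    cell_line: str = "",
) -> RBEEstimate:
    """Dispatch to the iso-survival or fixed-dose RBE for an EndpointSpec."""
    if endpoint.survival_level is not None:
        return rbe_at_survival(
            lq_x, lq_p, endpoint.survival_level, condition, cell_line
        )
    return rbe_at_dose(lq_x, lq_p, endpoint.proton_dose, condition, cell_line)
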