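"""Phenomenological and mechanistic proton RBE prediction models.

Three phenomenological models (McNamara, Rørvik unweighted, Jones-type)
share one dose-response skeleton: each defines the asymptotic limits
RBE_max (vanishing dose) and RBE_min (very large dose) as functions of
LET_d and the tissue's photon sensitivity, and the RBE at a proton dose
Dp follows from

    RBE = [sqrt((α/β)_x² + 4 Dp (α/β)_x RBE_max + 4 Dp² RBE_min²) − (α/β)_x]
          / (2 Dp)

The mechanistic repair-misrepair-fixation (RMF) route instead converts
the photon LQ parameters into proton LQ parameters using the
double-strand-break induction RBE (an external input) and the
frequency-mean specific energy z̄_F of the nucleus, then evaluates the
fixed-dose RBE from the converted parameters.

Model coefficients are data, not code: they live in a versioned YAML file
(``rbekit/data/model_coefficients.yaml``).  The McNamara and Rørvik sets
are the published proton coefficients; the Jones-type set is a synthetic
reconstruction calibrated against the published 2 Gy prediction table
(see the coefficient file header).
"""

from __future__ import annotations

import functools
import hashlib
import importlib.resources
import math

import numpy as np
import yaml

from .endpoints import rbe_fixed_dose
from .types import LQParameters, MaxMinPair, RBESource, RMFInputs, ValidationError

_COEFF_RESOURCE = importlib.resources.files("rbekit.data").joinpath(
    "model_coefficients.yaml"
)


@functools.lru_cache(maxsize=1)
def load_coefficients() -> dict:
    """Load the versioned model-coefficient file shipped with the package."""
    return yaml.safe_load(_COEFF_RESOURCE.read_text())


def coefficients_hash() -> str:
    """SHA-256 of the coefficient file, recorded in run manifests."""
    return hashlib.sha256(_COEFF_RESOURCE.read_bytes()).hexdigest()


def _check_inputs(alpha_over_beta_x: float, let_d: float) -> None:
    if not alpha_over_beta_x > 0:
        raise ValidationError(f"(α/β)_x must be > 0, got {alpha_over_beta_x}")
    if let_d < 0:
        raise ValidationError(f"LET_d must be >= 0, got {let_d}")


def mcn_maxmin(alpha_over_beta_x: float, let_d: float) -> MaxMinPair:
    """McNamara RBE_max/RBE_min at one ((α/β)_x, LET_d)."""
    _check_inputs(alpha_over_beta_x, let_d)
    c = load_coefficients()["mcn"]
    rbe_max = c["rbe_max_intercept"] + c["rbe_max_slope"] * let_d / alpha_over_beta_x
    rbe_min = c["rbe_min_intercept"] + c["rbe_min_slope"] * math.sqrt(
        alpha_over_beta_x
    ) * let_d
    return MaxMinPair(rbe_max=rbe_max, rbe_min=rbe_min, model=RBESource.MCN)


def ror_maxmin(alpha_over_beta_x: float, let_d: float) -> MaxMinPair:
    """Rørvik unweighted RBE_max (RBE_min is identically 1)."""
    _check_inputs(alpha_over_beta_x, let_d)
    lam = load_coefficients()["ror"]["lambda"]
    return MaxMinPair(
        rbe_max=1.0 + lam * let_d / alpha_over_beta_x,
        rbe_min=1.0,
        model=RBESource.ROR,
    )


def jon_maxmin(alpha_x: float, beta_x: float, let_d: float) -> MaxMinPair:
    """Jones-type RBE_max/RBE_min, depending on α_x and β_x separately."""
    if not alpha_x > 0 or not beta_x > 0:
        raise ValidationError("Jones model requires alpha_x > 0 and beta_x > 0")
    if let_d < 0:
        raise ValidationError(f"LET_d must be >= 0, got {let_d}")
    c = load_coefficients()["jon"]
    dl = let_d - c["let_offset"]
    return MaxMinPair(
        rbe_max=1.0 + c["rbe_max_slope"] * dl / math.sqrt(alpha_x),
        rbe_min=1.0 + c["rbe_min_slope"] * dl / math.sqrt(beta_x),
        model=RBESource.JON,
    )


def rbe_from_maxmin(dp: float, alpha_over_beta_x: float, pair: MaxMinPair) -> float:
    """RBE at proton dose Dp from the asymptotic pair (the shared skeleton)."""
    if not dp > 0:
        raise ValidationError(f"proton dose must be > 0, got {dp}")
    ab = alpha_over_beta_x
    if pair.rbe_max == pair.rbe_min:
        # the discriminant is the perfect square (ab + 2 Dp RBE_min)², so
        # the dose response collapses to the constant RBE_min exactly
        return pair.rbe_min
    disc = ab**2 + 4 * dp * ab * pair.rbe_max + 4 * dp**2 * pair.rbe_min**2
    return (math.sqrt(disc) - ab) / (2 * dp)


def predict_pheno(
    model: RBESource,
    dp: float,
    let_d: float,
    *,
    alpha_x: float | None = None,
    beta_x: float | None = None,
    alpha_over_beta_x: float | None = None,
) -> float:
    """Evaluate one phenomenological model at a proton dose.

    MCN and ROR need only ``alpha_over_beta_x`` (which may be the
    published rounded ratio rather than alpha_x/beta_x); JON additionally
    needs ``alpha_x`` and ``beta_x`` since its tissue dependence uses them
    separately.
    """
    if alpha_over_beta_x is not None:
        ab = alpha_over_beta_x
    elif alpha_x is not None and beta_x:
        ab = alpha_x / beta_x
    else:
        raise ValidationError("supply alpha_over_beta_x or alpha_x and beta_x")
    if model is RBESource.MCN:
        pair = mcn_maxmin(ab, let_d)
    elif model is RBESource.ROR:
        pair = ror_maxmin(ab, let_d)
    elif model is RBESource.JON:
        if alpha_x is None or beta_x is None:
            raise ValidationError("the Jones model needs alpha_x and beta_x")
        pair = jon_maxmin(alpha_x, beta_x, let_d)
    else:
        raise ValidationError(f"{model} is not a phenomenological model")
    return rbe_from_maxmin(dp, ab, pair)


def pheno_prediction_se(
    model: RBESource,
    dp: float,
    let_d: float,
    lq_x: LQParameters,
    alpha_over_beta_x: float | None = None,
) -> float:
    """Delta-method SE of a phenomenological prediction from the photon fit.

    Propagates the (α_x, β_x) covariance of the reference fit through the
    model; when a separately supplied (rounded) ratio anchors the
    evaluation, the perturbed ratio is scaled consistently with it.
    """
    ax0, bx0 = lq_x.alpha, lq_x.beta
    if bx0 == 0:
        return 0.0

    def f(ax, bx):
        ab = ax / bx
        if alpha_over_beta_x is not None:
            ab = alpha_over_beta_x * (ax / bx) / (ax0 / bx0)
        return predict_pheno(
            model, dp, let_d, alpha_x=ax, beta_x=bx, alpha_over_beta_x=ab
        )

    grad = np.zeros(2)
    for i, val in enumerate((ax0, bx0)):
        h = 1e-6 * max(abs(val), 1e-3)
        args_up = [ax0, bx0]
        args_dn = [ax0, bx0]
        args_up[i] += h
        args_dn[i] -= h
        grad[i] = (f(*args_up) - f(*args_dn)) / (2 * h)
    var = grad @ lq_x.covariance @ grad
    return float(var**0.5) if var > 0 else 0.0


#: keV/µm · µm⁻² → Gy conversion: 1 keV = 1.602e-16 J, 1 µm³ of unit
#: density water = 1e-15 kg, hence 0.1602 Gy per keV/µm per µm².
_KEV_PER_UM_TO_GY = 0.1602


def zbar_f(
    let_d: float, nucleus_diameter: float = 5.0, density: float = 1.0
) -> float:
    """Frequency-mean specific energy per event (Gy) in the cell nucleus.

    Site model of a cylindrical nucleus traversed face-on: the mean
    specific energy of one proton crossing is LET_d divided by the mass
    per unit path, z̄_F = 0.1602 · LET_d / (ρ · π d²/4) with d in µm and
    ρ in g/cm³.
    """
    if let_d < 0:
        raise ValidationError(f"LET_d must be >= 0, got {let_d}")
    if not nucleus_diameter > 0 or not density > 0:
        raise ValidationError("nucleus diameter and density must be > 0")
    area = math.pi * nucleus_diameter**2 / 4.0
    return _KEV_PER_UM_TO_GY * let_d / (density * area)


def rmf_lq_params(
    lq_x: LQParameters,
    rmf: RMFInputs,
    let_d: float,
    alpha_over_beta_x: float | None = None,
) -> LQParameters:
    """Convert photon LQ parameters to proton ones via the RMF relations.

        α_p = α_x · RBE_DSB · (1 + 2 z̄_F RBE_DSB / (α/β)_x)
        β_p = β_x · RBE_DSB²

    ``rmf.zbar_f`` overrides the site-model z̄_F computed from the nucleus
    diameter.  The resulting parameters feed the fixed-dose RBE formula.
    """
    ab = alpha_over_beta_x if alpha_over_beta_x is not None else lq_x.alpha_over_beta
    if not ab > 0 or not math.isfinite(ab):
        raise ValidationError("(α/β)_x must be positive and finite for RMF")
    z = rmf.zbar_f if rmf.zbar_f is not None else zbar_f(let_d, rmf.nucleus_diameter)
    r = rmf.rbe_dsb
    return LQParameters(
        alpha=lq_x.alpha * r * (1.0 + 2.0 * z * r / ab),
        beta=lq_x.beta * r * r,
    )


def predict_rmf(
    dp: float,
    lq_x: LQParameters,
    rmf: RMFInputs,
    let_d: float,
    alpha_over_beta_x: float | None = None,
) -> float:
    """RBE at proton dose Dp under the RMF conversion."""
    lq_p = rmf_lq_params(lq_x, rmf, let_d, alpha_over_beta_x)
    return rbe_fixed_dose(lq_x.alpha, lq_x.beta, lq_p.alpha, lq_p.beta, dp)
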