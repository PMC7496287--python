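"""Linear-quadratic survival-curve fitting.

Surviving fractions are normalised to the plating efficiency of the
unirradiated controls of the same session, then the LQ model
S(D) = exp(-αD - βD²) is fitted by 1/σ-weighted minimum chi-square with
non-negativity bounds on both parameters.  Parameter uncertainties come
from the curvature of the chi-square surface at the optimum (delta method
for derived quantities such as α/β).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .types import LQParameters, SurvivalPoint, SurvivalRecord, ValidationError

log = logging.getLogger(__name__)

#: Multi-start grid for the bounded chi-square minimisation; the lowest
#: chi-square among the converged starts is kept, which makes the fit
#: deterministic without a stated initialiser.
START_GRID = [(a, b) for a in (0.05, 0.2, 0.5) for b in (0.005, 0.03, 0.08)]

#: Default grouping columns identifying one survival curve.
CONDITION_KEYS = ("cell_line", "radiation", "let_d")


def records_to_frame(records: Iterable[SurvivalRecord]) -> pd.DataFrame:
    rows = [
        {
            "cell_line": r.cell_line,
            "radiation": r.radiation.value,
            "let_d": r.let_d,
            "depth_mm": r.depth_mm,
            "dose": r.dose,
            "cells_seeded": r.cells_seeded,
            "colonies": r.colonies,
            "session": r.session,
            "well": r.well,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def compute_surviving_fractions(
    records: Iterable[SurvivalRecord],
    group_keys: Sequence[str] = CONDITION_KEYS,
) -> pd.DataFrame:
    """Per-condition surviving fractions normalised to session controls.

    Within each group (by default one cell line and beam condition) the
    plating efficiency of a session is the mean per-well ``colonies /
    cells_seeded`` of its 0 Gy controls.  Every well's surviving fraction
    is its own colony ratio divided by the session plating efficiency;
    means and standard deviations are then aggregated per dose over all
    wells of all sessions.

    Returns a tidy frame with one row per (group, dose): columns
    ``dose, sf_mean, sf_sd, n_obs`` plus the grouping columns.  The 0 Gy
    rows are retained (their mean is 1 within each session by
    construction) but are excluded from fitting by :func:`fit_lq`.
    """
    df = records_to_frame(records)
    if df.empty:
        raise ValidationError("no survival records supplied")
    out = []
    for keys, group in df.groupby(list(group_keys), dropna=False):
        controls = group[group["dose"] == 0]
        if controls.empty:
            raise ValidationError(f"group {keys}: no 0 Gy control wells")
        pe, pe_relvar = {}, {}
        for session, ctrl in controls.groupby("session"):
            if (ctrl["colonies"] == 0).all():
                raise ValidationError(
                    f"group {keys}: control wells of session {session!r} "
                    "formed no colonies"
                )
            ratios = ctrl["colonies"] / ctrl["cells_seeded"]
            pe[session] = ratios.mean()
            # relative variance of the session's estimated plating
            # efficiency; Poisson fallback when only one control well
            if len(ratios) > 1:
                pe_relvar[session] = float(
                    ratios.var(ddof=1) / len(ratios) / ratios.mean() ** 2
                )
            else:
                pe_relvar[session] = 1.0 / max(float(ctrl["colonies"].sum()), 1.0)
        missing = set(group["session"]) - set(pe)
        if missing:
            raise ValidationError(
                f"group {keys}: sessions {sorted(missing)} have no controls"
            )
        sf = (group["colonies"] / group["cells_seeded"]) / group["session"].map(pe)
        for dose, idx in group.groupby("dose").groups.items():
            vals = sf.loc[idx]
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            if sd < 1e-12 * max(1.0, abs(float(vals.mean()))):
                sd = 0.0  # identical observations up to float rounding
            sess = group.loc[idx, "session"]
            # variance of the dose mean contributed by the shared
            # control-normalization error, weighted by session share
            weights = sess.value_counts(normalize=True)
            nrv = float(sum(w**2 * pe_relvar[s] for s, w in weights.items()))
            row = dict(zip(group_keys, keys if isinstance(keys, tuple) else (keys,)))
            row.update(
                dose=float(dose),
                sf_mean=float(vals.mean()),
                sf_sd=sd,
                n_obs=int(len(vals)),
                norm_rel_var=nrv,
            )
            out.append(row)
    return pd.DataFrame(out).sort_values([*group_keys, "dose"]).reset_index(drop=True)


def points_from_frame(frame: pd.DataFrame) -> list[SurvivalPoint]:
    """Convert rows of a surviving-fraction frame into SurvivalPoint objects."""
    return [
        SurvivalPoint(
            dose=float(r.dose),
            sf_mean=float(r.sf_mean),
            sf_sd=float(r.sf_sd),
            n_obs=int(r.n_obs),
            norm_rel_var=float(getattr(r, "norm_rel_var", 0.0)),
        )
        for r in frame.itertuples()
    ]


def _sigma_vector(points: Sequence[SurvivalPoint]) -> np.ndarray:
    """Weighting sigmas with a floor to avoid infinite weights.

    Zero (or tiny) per-dose scatter is floored at the smallest nonzero
    sigma of the curve, itself floored at 1e-4.
    """
    sd = np.array([p.sf_sd for p in points], dtype=float)
    nonzero = sd[sd > 0]
    floor = max(float(nonzero.min()) if nonzero.size else 0.0, 1e-4)
    return np.maximum(sd, floor)


def fit_lq(
    points: Sequence[SurvivalPoint],
    absolute_sigma: bool = False,
) -> LQParameters:
    """Weighted minimum chi-square fit of the LQ survival model.

    Minimises chi² = Σ [(SF_i − exp(−αD_i − βD_i²)) / σ_i]² over α, β ≥ 0,
    where σ_i is the per-dose standard deviation of the surviving fraction
    (the survival-curve error bars).  Points at 0 Gy are excluded: they
    define the plating-efficiency normalisation, not independent data.

    By default the parameter covariance is the sandwich estimate built
    from the curvature of the chi-square surface and the sampling
    variance of each mean surviving fraction (sf_sd²/n_obs).  This makes
    the standard errors invariant to the overall scale of the σ_i (i.e.
    to the SD-versus-SE-of-the-mean convention of the error bars) and
    avoids the small-sample noise of a reduced-chi-square rescaling.
    Pass ``absolute_sigma=True`` to instead take the σ_i at face value
    and return the plain inverse curvature, as in a textbook chi-square
    fit.
    """
    pts = [p for p in points if p.dose > 0]
    if len({p.dose for p in pts}) < 3:
        raise ValidationError("need at least 3 distinct positive dose levels")
    doses = np.array([p.dose for p in pts])
    sf = np.array([p.sf_mean for p in pts])
    if np.any(sf <= 0):
        raise ValidationError("surviving fractions must be positive")
    sd = np.array([p.sf_sd for p in pts])
    if np.all(sd == 0):
        log.warning("all sigmas are zero; falling back to unweighted least squares")
    sigma = _sigma_vector(pts)

    def residuals(theta):
        a, b = theta
        return (sf - np.exp(-a * doses - b * doses**2)) / sigma

    best = None
    for start in START_GRID:
        sol = least_squares(
            residuals, start, bounds=([0.0, 0.0], [np.inf, np.inf]), method="trf"
        )
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError(
            "LQ fit failed to converge from any of the "
            f"{len(START_GRID)} starting points (doses={doses.tolist()})"
        )
    alpha, beta = best.x
    chi2 = float(2 * best.cost)
    n = len(pts)
    dof = max(n - 2, 1)

    # Covariance from the Gauss-Newton curvature of chi²/2 at the optimum.
    jac = best.jac
    jtj = jac.T @ jac
    try:
        bread = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        bread = np.linalg.pinv(jtj)
    if absolute_sigma:
        cov = bread
    else:
        # Sandwich: per-point sampling variance of the means (sd²/n) plus
        # the rank-one curve-level covariance from the shared control
        # normalization, Cov(SF_i, SF_j) ≈ m_i m_j sqrt(v_i v_j).
        n_obs = np.array([p.n_obs for p in pts], dtype=float)
        var_mean = np.where(sd > 0, sd**2, sigma**2) / np.maximum(n_obs, 1.0)
        model_sf = np.exp(-alpha * doses - beta * doses**2)
        norm_sd = model_sf * np.sqrt([max(p.norm_rel_var, 0.0) for p in pts])
        v_resid = np.diag(var_mean) + np.outer(norm_sd, norm_sd)
        scaled = v_resid / np.outer(sigma, sigma)
        meat = jac.T @ scaled @ jac
        cov = bread @ meat @ bread
    log.info(
        "LQ fit: alpha=%.4f beta=%.4f chi2=%.4g (n=%d)", alpha, beta, chi2, n
    )
    return LQParameters(
        alpha=float(alpha),
        beta=float(beta),
        se_alpha=float(np.sqrt(max(cov[0, 0], 0.0))),
        se_beta=float(np.sqrt(max(cov[1, 1], 0.0))),
        cov_alpha_beta=float(cov[0, 1]),
        n_points=n,
        chi2=chi2,
    )


def propagate_ratio_error(lq: LQParameters) -> tuple[float, float]:
    """Delta-method mean and standard error of the ratio α/β.

    Var(α/β) = (1/β)² Var(α) + (α/β²)² Var(β) − 2 (α/β³) Cov(α, β).
    """
    if lq.beta == 0:
        raise ValidationError("alpha/beta undefined for beta = 0")
    a, b = lq.alpha, lq.beta
    var = (
        (1 / b) ** 2 * lq.se_alpha**2
        + (a / b**2) ** 2 * lq.se_beta**2
        - 2 * (a / b**3) * lq.cov_alpha_beta
    )
    return a / b, float(np.sqrt(max(var, 0.0)))


def fit_conditions(
    sf_frame: pd.DataFrame,
    group_keys: Sequence[str] = CONDITION_KEYS,
    absolute_sigma: bool = False,
) -> pd.DataFrame:
    """Fit one LQ curve per condition group of a surviving-fraction frame.

    Returns a tidy frame with the grouping columns plus the fitted
    parameters, their uncertainties and the delta-method α/β.
    """
    rows = []
    for keys, group in sf_frame.groupby(list(group_keys), dropna=False):
        lq = fit_lq(points_from_frame(group), absolute_sigma=absolute_sigma)
        row = dict(zip(group_keys, keys if isinstance(keys, tuple) else (keys,)))
        if lq.beta > 0:
            ab, ab_se = propagate_ratio_error(lq)
        else:
            ab, ab_se = float("inf"), float("nan")
        row.update(
            alpha=lq.alpha,
            beta=lq.beta,
            se_alpha=lq.se_alpha,
            se_beta=lq.se_beta,
            cov_alpha_beta=lq.cov_alpha_beta,
            alpha_over_beta=ab,
            se_alpha_over_beta=ab_se,
            n_points=lq.n_points,
            chi2=lq.chi2,
        )
        rows.append(row)
    return pd.DataFrame(rows).sort_values(list(group_keys)).reset_index(drop=True)
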