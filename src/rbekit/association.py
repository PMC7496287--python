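"""LET_d–RBE association by linear regression with an F-test on the slope.

For each cell line and endpoint the mean RBE values are regressed on
LET_d by ordinary least squares and the null hypothesis of zero slope is
tested with the F-statistic on (1, n−2) degrees of freedom — equivalently
the square of the slope t-statistic.  An inverse-variance weighted
variant is available for estimates carrying standard errors.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import statsmodels.api as sm

from .types import EndpointSpec, RBEEstimate, RegressionResult, ValidationError


def fit_rbe_vs_letd(
    estimates: Sequence[RBEEstimate],
    weighted: bool = False,
) -> RegressionResult:
    """Regress one cell line's RBE estimates on LET_d.

    ``weighted=True`` uses 1/se² weights (wells with se == 0 are
    rejected); the default is the unweighted fit of the mean values.
    """
    if len(estimates) < 3:
        raise ValidationError("regression needs at least 3 RBE estimates")
    let = np.array([e.condition.let_d for e in estimates], dtype=float)
    if len(np.unique(let)) < 3:
        raise ValidationError("need at least 3 distinct LET_d values")
    endpoints = {e.endpoint for e in estimates}
    if len(endpoints) != 1:
        raise ValidationError("estimates mix different endpoints")
    cells = {e.cell_line for e in estimates}
    if len(cells) != 1:
        raise ValidationError("estimates mix different cell lines")
    y = np.array([e.value for e in estimates], dtype=float)
    X = sm.add_constant(let)
    if weighted:
        se = np.array([e.se for e in estimates], dtype=float)
        if np.any(se <= 0):
            raise ValidationError("weighted fit requires positive standard errors")
        res = sm.WLS(y, X, weights=1.0 / se**2).fit()
    else:
        res = sm.OLS(y, X).fit()
    f_stat = float(res.fvalue)
    p_value = float(res.f_pvalue)
    if not np.isfinite(f_stat) or f_stat <= 0:  # exactly constant response
        f_stat, p_value = 0.0, 1.0
    return RegressionResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        f_stat=f_stat,
        p_value=min(max(p_value, np.nextafter(0, 1)), 1.0),
        n=len(estimates),
        endpoint=next(iter(endpoints)),
        cell_line=next(iter(cells)),
        se_slope=float(res.bse[1]),
    )


def regress_groups(estimates: Sequence[RBEEstimate], weighted: bool = False):
    """Run the LET_d regression per (cell_line, endpoint, source) group."""
    groups: dict[tuple, list[RBEEstimate]] = {}
    for e in estimates:
        groups.setdefault((e.cell_line, e.endpoint, e.source), []).append(e)
    results = []
    for (cell, endpoint, source), ests in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][1].label, kv[0][2].value)
    ):
        if len({e.condition.let_d for e in ests}) < 3:
            continue
        results.append((source, fit_rbe_vs_letd(ests, weighted=weighted)))
    return results
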