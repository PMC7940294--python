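"""Continuous responses of community and reproductive metrics to land use.

Plot-level metrics are regressed on each land-use parameter within one
habitat (and region, where the regions are analyzed apart): Gaussian
metrics (diversity, density, size CWM) by ordinary least squares,
proportions (sexual individuals, females, gravid females) by binomial GLM
with logit link, and egg counts per gravid female by Poisson GLM with log
link. Direction arrows are assigned only below the two-sided 0.05
threshold, uncorrected — mirroring how such effect tables are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .records import ValidationError

ALPHA = 0.05


@dataclass(frozen=True)
class ResponseResult:
    """Slope, p-value and direction of one metric against one gradient."""

    response: str
    parameter: str
    slope: float
    p_value: float | None
    direction: str  # "up" / "down" / "ns"
    family: str  # "gaussian-linear" / "binomial" / "poisson"
    n: int
    habitat: str | None = None
    region: str | None = None
    separation: bool = False

    @property
    def arrow(self) -> str:
        return {"up": "↑", "down": "↓", "ns": ""}[self.direction]


def _direction(slope: float, p: float | None, alpha: float = ALPHA) -> str:
    if p is None or not np.isfinite(p) or p >= alpha:
        return "ns"
    return "up" if slope > 0 else "down"


def _check_xy(x, n_y: int, min_n: int = 3) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size != n_y:
        raise ValidationError("response and gradient must be index-aligned")
    if x.size < min_n:
        raise ValidationError(f"need at least {min_n} plots, got {x.size}")
    if not np.isfinite(x).all():
        raise ValidationError("gradient values must be finite")
    if np.ptp(x) == 0:
        raise ValidationError("gradient has zero variance")
    return x


def linear_response(
    y, x, response: str = "", parameter: str = "", **meta
) -> ResponseResult:
    """OLS slope of a per-plot metric on a gradient, with t-test p-value."""
    y = np.asarray(y, dtype=float)
    x = _check_xy(x, y.size)
    if not np.isfinite(y).all():
        raise ValidationError("response values must be finite")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    slope, p = float(fit.params[1]), float(fit.pvalues[1])
    return ResponseResult(
        response=response,
        parameter=parameter,
        slope=slope,
        p_value=p,
        direction=_direction(slope, p),
        family="gaussian-linear",
        n=y.size,
        **meta,
    )


def proportion_response(
    successes, totals, x, response: str = "", parameter: str = "", **meta
) -> ResponseResult:
    """Binomial (logit) regression of per-plot proportions on a gradient.

    Complete separation (all successes or all failures, or a separating
    gradient) yields a flagged result with an absent p-value rather than a
    spuriously tiny one.
    """
    k = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if k.shape != n.shape:
        raise ValidationError("successes and totals must be index-aligned")
    if (n < 1).any():
        raise ValidationError("totals must be >= 1 on every plot")
    if (k < 0).any() or (k > n).any():
        raise ValidationError("successes must lie in [0, totals]")
    x = _check_xy(x, k.size)
    if (k == n).all() or (k == 0).all():
        return ResponseResult(
            response=response, parameter=parameter, slope=np.nan, p_value=None,
            direction="ns", family="binomial", n=k.size, separation=True, **meta,
        )
    endog = np.column_stack([k, n - k])
    try:
        fit = sm.GLM(endog, sm.add_constant(x), family=sm.families.Binomial()).fit()
        slope, p = float(fit.params[1]), float(fit.pvalues[1])
        separation = not np.isfinite(fit.bse[1]) or abs(slope) > 50
    except Exception:
        slope, p, separation = np.nan, None, True
    if separation:
        p = None
    return ResponseResult(
        response=response,
        parameter=parameter,
        slope=slope,
        p_value=p,
        direction=_direction(slope, p),
        family="binomial",
        n=k.size,
        separation=separation,
        **meta,
    )


def count_response(
    counts, x, response: str = "", parameter: str = "", **meta
) -> ResponseResult:
    """Poisson (log link) regression of counts on a gradient (Wald p-value)."""
    y = np.asarray(counts, dtype=float)
    if (y < 0).any():
        raise ValidationError("counts must be >= 0")
    x = _check_xy(x, y.size)
    fit = sm.GLM(y, sm.add_constant(x), family=sm.families.Poisson()).fit()
    slope, p = float(fit.params[1]), float(fit.pvalues[1])
    return ResponseResult(
        response=response,
        parameter=parameter,
        slope=slope,
        p_value=p,
        direction=_direction(slope, p),
        family="poisson",
        n=y.size,
        **meta,
    )


def response_table(
    metrics: pd.DataFrame,
    gradients: pd.DataFrame,
    families: dict[str, str] | None = None,
    proportion_cols: dict[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Cross every metric with every gradient; one tidy row per pair.

    ``metrics`` and ``gradients`` are per-plot tables sharing their index
    (plot ids). ``families`` maps metric name -> family (default
    gaussian-linear); binomial metrics are named in ``proportion_cols`` as
    metric -> (successes column, totals column) pairs of ``metrics``.
    Rows with a missing metric value are dropped pairwise.
    """
    families = families or {}
    proportion_cols = proportion_cols or {}
    metrics, gradients = metrics.align(gradients, join="inner", axis=0)
    results = []
    metric_names = [
        c
        for c in metrics.columns
        if c not in {tc for pair in proportion_cols.values() for tc in pair}
    ] + list(proportion_cols)
    for name in metric_names:
        family = families.get(name, "binomial" if name in proportion_cols else "gaussian-linear")
        for param in gradients.columns:
            x_all = gradients[param]
            if name in proportion_cols:
                kcol, ncol = proportion_cols[name]
                ok = metrics[kcol].notna() & metrics[ncol].notna() & x_all.notna()
                if ok.sum() < 3:
                    continue
                res = proportion_response(
                    metrics.loc[ok, kcol], metrics.loc[ok, ncol], x_all[ok],
                    response=name, parameter=param,
                )
            else:
                ok = metrics[name].notna() & x_all.notna()
                if ok.sum() < 3:
                    continue
                y, x = metrics.loc[ok, name], x_all[ok]
                if family == "poisson":
                    res = count_response(y, x, response=name, parameter=param)
                else:
                    res = linear_response(y, x, response=name, parameter=param)
            results.append(res.__dict__ | {"arrow": res.arrow})
    return pd.DataFrame(results)


def render_arrows(table: pd.DataFrame) -> str:
    """Plain-text metric x parameter grid of significance arrows."""
    if table.empty:
        return "(no responses)"
    wide = table.pivot_table(
        index="response", columns="parameter", values="arrow", aggfunc="first"
    ).fillna("")
    return wide.to_string()
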