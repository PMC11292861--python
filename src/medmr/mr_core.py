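"""Two-sample MR estimators and sensitivity diagnostics.

All estimators consume harmonized per-variant effect pairs
``(beta_exp, se_exp, beta_out, se_out)`` — either a
:class:`~medmr.harmonize.HarmonizedSet` or any DataFrame with those
columns — and return an :class:`MREstimate` whose ``beta`` is the causal
log odds (or SD change) in the outcome per SD of exposure.

Implemented methods
-------------------
wald_ratio        per-variant ratio estimate beta_out / beta_exp
ivw               inverse-variance-weighted meta-analysis of Wald ratios,
                  i.e. weighted regression through the origin; fixed or
                  multiplicative-random-effects standard errors
mr_egger          weighted regression *with* an intercept; the intercept
                  estimates directional pleiotropy, the slope the causal
                  effect (inference on t with n-2 df)
weighted_median   weight-interpolated median of the Wald ratios; consistent
                  while valid instruments carry >50% of the weight
mode_estimate     kernel-density mode of the Wald ratios (simple/weighted)
cochran_q         heterogeneity test of the Wald ratios
leave_one_out     influence diagnostics by single-variant deletion

The ratio variance used for the median, modes and Q is the first-order
delta approximation ``se_out²/beta_exp²``; pass ``second_order=True`` to
add the ``beta_out²·se_exp²/beta_exp⁴`` term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    DegenerateDesignError,
    DegenerateInstrumentError,
    DomainError,
    InsufficientInstrumentsError,
)

_TINY_P = 5e-324  # p-values are clamped into (0, 1]


def _clamp_p(p: float) -> float:
    if not np.isfinite(p):
        return _TINY_P
    return float(min(max(p, _TINY_P), 1.0))


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate with OR-scale reporting."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    or_point: float
    or_ci_low: float
    or_ci_high: float


def beta_to_or(beta: float, se: float):
    """Log-odds estimate → odds ratio with 95% CI ``exp(beta ± 1.96·se)``."""
    if not se > 0:
        raise DomainError(f"se must be > 0, got {se}")
    return math.exp(beta), math.exp(beta - 1.96 * se), math.exp(beta + 1.96 * se)


def percent_change(beta: float) -> float:
    """Percent change in odds per unit exposure: ``(exp(beta) - 1) · 100``.

    Negative values are risk reductions (e.g. beta = -0.30 → -25.9, a 26%
    reduction when rounded to the nearest percent).
    """
    return (math.exp(beta) - 1.0) * 100.0


def _make_estimate(method: str, beta: float, se: float, n_snp: int,
                   pval: float | None = None, df: int | None = None) -> MREstimate:
    se = float(se)
    if pval is None:
        if se > 0:
            z = beta / se
            pval = 2 * stats.t.sf(abs(z), df) if df is not None else 2 * stats.norm.sf(abs(z))
        else:
            pval = _TINY_P if beta != 0 else 1.0
    se_ci = max(se, 0.0)
    return MREstimate(
        method=method,
        beta=float(beta),
        se=se,
        pval=_clamp_p(pval),
        n_snp=int(n_snp),
        or_point=math.exp(beta),
        or_ci_low=math.exp(beta - 1.96 * se_ci),
        or_ci_high=math.exp(beta + 1.96 * se_ci),
    )


def _mr_arrays(h):
    """Extract (beta_exp, se_exp, beta_out, se_out) from a HarmonizedSet or frame."""
    frame = h.mr_frame if hasattr(h, "mr_frame") else h
    cols = ("beta_exp", "se_exp", "beta_out", "se_out")
    return tuple(np.asarray(frame[c], dtype=float) for c in cols)


def _ratio_stats(h, second_order: bool = False):
    """Per-variant Wald ratios and their (delta-method) variances."""
    bx, sx, by, sy = _mr_arrays(h)
    if (bx == 0).any():
        raise DegenerateInstrumentError("beta_exp = 0 for at least one instrument")
    ratios = by / bx
    var = sy**2 / bx**2
    if second_order:
        var = var + by**2 * sx**2 / bx**4
    return ratios, var


def wald_ratio(beta_exp: float, se_exp: float, beta_out: float, se_out: float) -> MREstimate:
    """Single-instrument causal estimate ``beta_out / beta_exp``.

    The standard error is first-order: ``se_out / |beta_exp|``.
    """
    if beta_exp == 0:
        raise DegenerateInstrumentError("beta_exp = 0")
    if se_out <= 0 or se_exp <= 0:
        raise DomainError("standard errors must be > 0")
    beta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    return _make_estimate("wald_ratio", beta, se, n_snp=1)


def ivw(h, effects: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate.

    Weighted regression of ``beta_out`` on ``beta_exp`` through the origin
    with weights ``1/se_out²``.  ``effects="fixed"`` uses the closed-form
    fixed-effect standard error; ``"multiplicative_random"`` (default)
    scales it by ``max(1, sqrt(Q/(n-1)))`` and needs at least two variants.
    """
    if effects not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown effects model {effects!r}")
    bx, _sx, by, sy = _mr_arrays(h)
    n = len(bx)
    need = 2 if effects == "multiplicative_random" else 1
    if n < need:
        raise InsufficientInstrumentsError(f"IVW ({effects}) needs >= {need} variants, got {n}")
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx * bx))
    if denom == 0:
        raise DegenerateInstrumentError("all beta_exp are zero")
    beta = float(np.sum(w * bx * by)) / denom
    se = denom ** -0.5
    method = "ivw_fixed"
    if effects == "multiplicative_random":
        q = float(np.sum(w * (by - beta * bx) ** 2))
        se *= max(1.0, math.sqrt(q / (n - 1)))
        method = "ivw_mre"
    return _make_estimate(method, beta, se, n_snp=n)


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger slope (causal estimate) and intercept (pleiotropy) pair."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


def mr_egger(h) -> EggerResult:
    """MR-Egger regression.

    Weighted least squares of ``beta_out`` on ``beta_exp`` with an
    intercept, weights ``1/se_out²``, after orienting every pair so that
    ``beta_exp >= 0``.  Slope and intercept are tested on t with n-2 df.
    A non-null intercept indicates directional pleiotropy.
    """
    bx, _sx, by, sy = _mr_arrays(h)
    n = len(bx)
    if n < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 variants, got {n}")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    if np.ptp(bx) == 0:
        raise DegenerateDesignError("all beta_exp identical after orientation")
    res = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
    icept, slope = res.params
    icept_se, slope_se = res.bse
    slope_est = _make_estimate("egger", slope, slope_se, n_snp=n,
                               pval=res.pvalues[1] if np.isfinite(res.pvalues[1]) else None)
    return EggerResult(
        slope=slope_est,
        intercept=float(icept),
        intercept_se=float(icept_se),
        intercept_pval=_clamp_p(res.pvalues[0]),
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Value at cumulative weight 0.5, interpolating between order statistics."""
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    cw = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cw, r))


def weighted_median(h, n_boot: int = 1000, seed: int | None = None,
                    second_order: bool = False) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap standard error.

    Ratios are weighted by their inverse variances; the estimate is the
    interpolated weighted median.  The SE resamples each ratio from its
    normal sampling distribution ``n_boot`` times (``seed`` required for
    reproducibility).
    """
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    ratios, var = _ratio_stats(h, second_order=second_order)
    n = len(ratios)
    if n < 3:
        raise InsufficientInstrumentsError(f"weighted median needs >= 3 variants, got {n}")
    weights = 1.0 / var
    beta = _weighted_median_point(ratios, weights)
    rng = np.random.default_rng(seed)
    draws = ratios + rng.standard_normal((n_boot, n)) * np.sqrt(var)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = _weighted_median_point(draws[b], weights)
    se = float(np.std(boots, ddof=1))
    return _make_estimate("weighted_median", beta, se, n_snp=n)


def _kde_mode(ratios: np.ndarray, weights: np.ndarray, bandwidth_factor: float) -> float:
    """Argmax of a normal-kernel density with a MAD-based bandwidth."""
    if np.ptp(ratios) == 0:
        return float(ratios[0])
    mad = float(np.median(np.abs(ratios - np.median(ratios))))
    s = 1.4826 * mad
    if s == 0:
        s = float(np.std(ratios))
    h = bandwidth_factor * 0.9 * s * len(ratios) ** (-1 / 5)
    if h <= 0:
        return float(np.median(ratios))
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 2048)
    dens = (weights[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def mode_estimate(h, weighted: bool = True, bandwidth_factor: float = 1.0,
                  n_boot: int = 1000, seed: int | None = None,
                  second_order: bool = False) -> MREstimate:
    """Mode-based estimator (simple or inverse-variance weighted).

    The causal estimate is the argmax of a normal-kernel smoothed density
    of the Wald ratios; bandwidth is ``bandwidth_factor × 0.9·(1.4826·MAD)·
    n^(-1/5)``.  SE by seeded parametric bootstrap.
    """
    if seed is None:
        raise ValueError("mode_estimate requires an explicit seed")
    ratios, var = _ratio_stats(h, second_order=second_order)
    n = len(ratios)
    if n < 3:
        raise InsufficientInstrumentsError(f"mode estimator needs >= 3 variants, got {n}")
    weights = (1.0 / var) if weighted else np.ones(n)
    weights = weights / weights.sum()
    beta = _kde_mode(ratios, weights, bandwidth_factor)

    rng = np.random.default_rng(seed)
    draws = ratios + rng.standard_normal((n_boot, n)) * np.sqrt(var)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = _kde_mode(draws[b], weights, bandwidth_factor)
    se = float(np.std(boots, ddof=1))
    return _make_estimate("weighted_mode" if weighted else "simple_mode", beta, se, n_snp=n)


def cochran_q(h, second_order: bool = False):
    """Cochran's Q heterogeneity test of the Wald ratios.

    ``Q = Σ wj (ratio_j − beta_IVW_fixed)²`` with inverse-ratio-variance
    weights; df = n − 1; upper-tail chi-square p-value.
    Returns ``(Q, df, pval)``.
    """
    ratios, var = _ratio_stats(h, second_order=second_order)
    n = len(ratios)
    if n < 2:
        raise InsufficientInstrumentsError(f"Cochran's Q needs >= 2 variants, got {n}")
    w = 1.0 / var
    beta_fixed = float(np.sum(w * ratios) / np.sum(w))
    q = float(np.sum(w * (ratios - beta_fixed) ** 2))
    df = n - 1
    return q, df, _clamp_p(stats.chi2.sf(q, df))


def leave_one_out(h, effects: str = "multiplicative_random") -> pd.DataFrame:
    """IVW re-estimated with each variant removed in turn.

    A variant is flagged ``influential`` when dropping it changes the sign
    of the all-variant estimate or its nominal significance (p < 0.05).
    """
    frame = h.mr_frame if hasattr(h, "mr_frame") else pd.DataFrame(h).reset_index(drop=True)
    n = len(frame)
    if n < 3:
        raise InsufficientInstrumentsError(f"leave-one-out needs >= 3 variants, got {n}")
    full = ivw(frame, effects=effects)
    rows = []
    for i in range(n):
        sub = frame.drop(index=frame.index[i])
        est = ivw(sub, effects=effects)
        rows.append(
            {
                "excluded": frame["variant_id"].iloc[i] if "variant_id" in frame else str(i),
                "beta": est.beta,
                "se": est.se,
                "pval": est.pval,
                "influential": (np.sign(est.beta) != np.sign(full.beta))
                or ((est.pval < 0.05) != (full.pval < 0.05)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SensitivityReport:
    """Heterogeneity, pleiotropy and influence diagnostics for one MR."""

    cochran_q: float
    q_df: int
    q_pval: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_pval: float
    leave_one_out: pd.DataFrame


def sensitivity_report(h) -> SensitivityReport:
    """Bundle Cochran's Q, the Egger intercept test and leave-one-out."""
    q, df, q_p = cochran_q(h)
    egger = mr_egger(h)
    loo = leave_one_out(h)
    return SensitivityReport(
        cochran_q=q,
        q_df=df,
        q_pval=q_p,
        egger_intercept=egger.intercept,
        egger_intercept_se=egger.intercept_se,
        egger_intercept_pval=egger.intercept_pval,
        leave_one_out=loo,
    )
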