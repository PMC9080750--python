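"""Inference on fitted pause models: model selection, tests, contrasts.

Covers the analysis chain applied to the post-buzz pause: AICc ranking of
candidate models (outcome only vs. added weather or temperature), a
likelihood-ratio test of the selected model against its random-effects-only
null, a type-II Wald chi-square test per fixed factor, Bonferroni-adjusted
pairwise rate-ratio contrasts between outcome levels, and
truncation-corrected estimated means with 95% confidence intervals.

Contrast degrees of freedom follow the residual convention
df = n_obs - n_params with n_params counting fixed effects plus variance
components; p-values for contrasts use the t distribution at that df.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glmm import ZeroTruncatedPoissonGLMM
from .ztp import ztp_mean, ztp_rvs

__all__ = [
    "TestResult",
    "ContrastResult",
    "model_select",
    "lrt_vs_null",
    "wald_type2",
    "pairwise_contrasts",
    "estimated_means",
    "outcome_proportions",
    "dispersion_check",
]


@dataclass
class TestResult:
    """A chi-square test: statistic, degrees of freedom, p-value."""

    statistic: float
    df: int
    p: float


@dataclass
class ContrastResult:
    """One pairwise rate-ratio contrast on the response scale.

    ``ratio`` is exp(eta_a - eta_b); its delta-method standard error is
    ratio * SE(eta_a - eta_b); ``p_adjusted`` is Bonferroni over the number
    of pairs tested together.
    """

    pair: tuple
    ratio: float
    se: float
    df: int
    p_raw: float
    p_adjusted: float
    estimable: bool = True


def _check_fitted(fit):
    if not hasattr(fit, "coef_"):
        raise ValueError("model is not fitted")


def model_select(fits, labels=None):
    """AICc comparison table, best model first.

    All fits must be on the same data (equal ``n_obs_``); ties in AICc are
    broken in favour of fewer parameters.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    for f in fits:
        _check_fitted(f)
    n0 = fits[0].n_obs_
    if any(f.n_obs_ != n0 for f in fits):
        raise ValueError("fits were not computed on identical data (n_obs differ)")
    if labels is None:
        labels = ["+".join(f.fixed) if f.fixed else "null" for f in fits]
    tab = pd.DataFrame(
        {
            "model": labels,
            "k": [f.n_params_ for f in fits],
            "logLik": [f.loglik_ for f in fits],
            "AICc": [f.aicc_ for f in fits],
        }
    ).sort_values(["AICc", "k"], kind="mergesort", ignore_index=True)
    tab["dAICc"] = tab["AICc"] - tab["AICc"].iloc[0]
    return tab


def lrt_vs_null(fit, null):
    """Likelihood-ratio chi-square of a model against its nested null.

    ``null`` must drop fixed effects only (same data, same random terms);
    df is the difference in fixed-effect counts.
    """
    _check_fitted(fit)
    _check_fitted(null)
    if null.n_obs_ != fit.n_obs_:
        raise ValueError("models were fitted to different data")
    if tuple(null.random or ()) != tuple(fit.random or ()):
        raise ValueError("null must keep the same random-effect structure")
    if not set(null.fixed) <= set(fit.fixed):
        raise ValueError("null model is not nested in the full model")
    df = len(fit.coef_) - len(null.coef_)
    if df < 0:
        raise ValueError("null model has more fixed effects than the full model")
    stat = max(0.0, 2.0 * (fit.loglik_ - null.loglik_))
    return TestResult(statistic=stat, df=df, p=float(stats.chi2.sf(stat, df)) if df else 1.0)


def wald_type2(fit, factor="outcome"):
    """Type-II Wald chi-square for one term's coefficient block.

    In an additive model the type-II test of a term is the Wald test of its
    coefficients in the full fit (every other term already adjusted for):
    chi2 = b' V^-1 b over the block, df = block size.
    """
    _check_fitted(fit)
    if factor not in fit.term_slices_ or factor == "(Intercept)":
        raise ValueError(f"term {factor!r} not in the fitted model")
    sl = fit.term_slices_[factor]
    b = fit.coef_[sl]
    V = fit.vcov_[sl, sl]
    if not np.all(np.isfinite(V)):
        raise ValueError("singular or unavailable covariance block for the term")
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as err:
        raise ValueError("singular covariance block for the term") from err
    df = len(b)
    return TestResult(statistic=stat, df=df, p=float(stats.chi2.sf(stat, df)))


def _level_predictor(fit, factor, level):
    """Contrast vector picking the linear predictor of one factor level."""
    c = np.zeros(len(fit.coef_))
    c[0] = 1.0
    levels = fit.term_levels_[factor]
    if level != levels[0]:
        c[fit.term_slices_[factor].start + levels[1:].index(level)] = 1.0
    return c


def estimated_means(fit, factor="outcome", conf_level=0.95):
    """Truncation-corrected estimated mean per factor level with Wald CIs.

    The linear predictor per level (other covariates at reference/zero,
    random effects at zero) maps to the response scale through the ZTP mean
    lam/(1-e^-lam); the CI back-transforms eta +/- z * SE(eta).
    """
    _check_fitted(fit)
    if factor not in fit.term_levels_:
        raise ValueError(f"{factor!r} is not a factor in the model")
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    rows = []
    for level in fit.term_levels_[factor]:
        c = _level_predictor(fit, factor, level)
        eta = float(c @ fit.coef_)
        se = float(np.sqrt(c @ fit.vcov_ @ c))
        rows.append(
            {
                "level": level,
                "mean": ztp_mean(np.exp(eta)),
                "ci_low": ztp_mean(np.exp(eta - z * se)),
                "ci_high": ztp_mean(np.exp(eta + z * se)),
            }
        )
    return pd.DataFrame(rows)


def pairwise_contrasts(fit, factor="outcome", adjust="bonferroni"):
    """All pairwise rate-ratio contrasts between the factor's levels.

    For each ordered pair (a, b): ratio = exp(eta_a - eta_b), delta-method
    SE, two-sided t test at df = n_obs - n_params, and the Bonferroni
    adjustment over the number of pairs.
    """
    _check_fitted(fit)
    if factor not in fit.term_levels_:
        raise ValueError(f"{factor!r} is not a factor in the model")
    levels = fit.term_levels_[factor]
    pairs = list(itertools.combinations(levels, 2))
    df = fit.n_obs_ - fit.n_params_
    out = []
    for a, b in pairs:
        c = _level_predictor(fit, factor, a) - _level_predictor(fit, factor, b)
        delta = float(c @ fit.coef_)
        var = float(c @ fit.vcov_ @ c)
        if not np.isfinite(var) or var < 0:
            out.append(ContrastResult((a, b), np.nan, np.nan, df, np.nan, np.nan, False))
            continue
        se_delta = np.sqrt(var)
        ratio = float(np.exp(delta))
        if se_delta == 0.0:
            p_raw = 1.0 if delta == 0.0 else 0.0
        else:
            p_raw = float(2.0 * stats.t.sf(abs(delta) / se_delta, df))
        p_adj = min(1.0, len(pairs) * p_raw) if adjust == "bonferroni" else p_raw
        out.append(
            ContrastResult(
                pair=(a, b), ratio=ratio, se=ratio * se_delta, df=df,
                p_raw=p_raw, p_adjusted=p_adj,
            )
        )
    return out


def outcome_proportions(counts):
    """Percentage of attacks per outcome, to one decimal place.

    ``counts`` is a mapping level -> count or an attack table with an
    ``outcome`` column.
    """
    if isinstance(counts, pd.DataFrame):
        counts = counts["outcome"].value_counts().to_dict()
    total = sum(counts.values())
    if total == 0:
        return {k: float("nan") for k in counts}
    return {k: round(100.0 * v / total, 1) for k, v in counts.items()}


def dispersion_check(fit, data, n_sim=200, rng=None):
    """Simulation-based dispersion diagnostic (informational).

    Compares the variance of Pearson residuals of the observed data with
    its distribution under the fitted model (random effects at zero),
    re-simulating the response ``n_sim`` times.  Returns the observed
    statistic, the simulated mean, and a two-sided simulation p-value.
    """
    _check_fitted(fit)
    if rng is None:
        rng = np.random.default_rng()
    data = pd.DataFrame(data).reset_index(drop=True)
    y = data[fit.response].to_numpy(float)
    lam = np.exp(fit.linear_predictor(data))
    mu = ztp_mean(lam)
    var = mu * (1.0 + lam - mu)  # ZTP variance
    obs = float(np.var((y - mu) / np.sqrt(var), ddof=1))
    sims = np.empty(n_sim)
    for s in range(n_sim):
        ysim = ztp_rvs(lam, rng=rng)
        sims[s] = np.var((ysim - mu) / np.sqrt(var), ddof=1)
    p = 2.0 * min((sims >= obs).mean(), (sims <= obs).mean())
    return {"statistic": obs, "simulated_mean": float(sims.mean()), "p": min(1.0, float(p))}
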