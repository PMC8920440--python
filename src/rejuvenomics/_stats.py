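"""Shared statistical machinery: empirical-Bayes variance shrinkage and t->z mapping.

The moderated-t construction pools information across features: per-feature sample
variances s_g^2 on d residual degrees of freedom are assumed s_g^2 | sigma_g^2 ~
scaled chi^2, with 1/sigma_g^2 drawn from a scaled chi^2 prior of d0 degrees of
freedom and scale s0^2.  The posterior variance (d0*s0^2 + d*s_g^2)/(d0 + d)
replaces s_g^2 in the t statistic, which then has d + d0 degrees of freedom.
(d0, s0^2) are fitted by moment-matching on log sample variances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = ["VarianceShrinkage", "squeeze_variances", "t_to_z", "bh_adjust"]


@dataclass
class VarianceShrinkage:
    """Result of empirical-Bayes variance moderation."""

    d0: float  # prior degrees of freedom (may be inf)
    s0_sq: float  # prior variance scale
    var_post: np.ndarray  # posterior (shrunken) variances per feature
    df_total: float  # d + d0, degrees of freedom of the moderated t
    zero_variance: np.ndarray  # mask of features with zero sample variance


def _trigamma_inverse(x: float, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def squeeze_variances(s_sq: np.ndarray, df: float) -> VarianceShrinkage:
    """Fit the scaled-F prior to sample variances and return posterior variances.

    Moment matching on log variances: e_g = log(s_g^2) - digamma(d/2) + log(d/2)
    has mean log(s0^2) + digamma(d0/2) - log(d0/2) and excess variance
    trigamma(d0/2) beyond the trigamma(d/2) sampling term.
    """
    s_sq = np.asarray(s_sq, dtype=float)
    zero = s_sq <= 0
    if df < 1:
        raise ValueError("residual degrees of freedom must be >= 1")
    work = s_sq.copy()
    if zero.all():
        raise ValueError("all features have zero residual variance")
    # zero variances carry no log-scale information; exclude from the fit
    logs = np.log(work[~zero])
    e = logs - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_bar = float(np.mean(e))
    n = e.size
    if n > 1:
        excess = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    else:
        excess = -1.0
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(e_bar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_bar))
    if np.isinf(d0):
        var_post = np.full_like(s_sq, s0_sq)
    else:
        var_post = (d0 * s0_sq + df * s_sq) / (d0 + df)
    # zero-variance features receive the shrunken floor
    if np.isinf(d0):
        var_post[zero] = s0_sq
    else:
        var_post[zero] = d0 * s0_sq / (d0 + df)
    return VarianceShrinkage(
        d0=d0,
        s0_sq=s0_sq,
        var_post=var_post,
        df_total=df + d0,
        zero_variance=zero,
    )


def t_to_z(t: np.ndarray, df: float) -> np.ndarray:
    """Map t statistics to standard-normal quantiles with matched tail areas.

    Uses the survival function on the |t| side for numerical stability in the
    far tails; the sign of t is preserved.  df = inf returns t unchanged.
    """
    t = np.asarray(t, dtype=float)
    if np.isinf(df):
        return t.copy()
    tail = stats.t.sf(np.abs(t), df)
    # sf can underflow to 0 for |t| huge; cap at the smallest positive double
    tail = np.clip(tail, np.finfo(float).tiny, 0.5)
    z = stats.norm.isf(tail)
    return np.sign(t) * z


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out
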