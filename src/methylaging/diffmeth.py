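"""Differential methylation with empirical-Bayes variance moderation.

Two-group comparison of M-values using the moderated t-statistic: per-probe
sample variances are shrunk toward a prior variance s0^2 with prior degrees
of freedom d0, both estimated from the cohort by the method of moments on
log sample variances (the scaled-chi-square hierarchical model underlying
the limma family of methods). The moderated statistic is

    t~_g = (mean1_g - mean2_g) / (s~_g * sqrt(1/n1 + 1/n2)),
    s~_g^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d),

referred to a t distribution with d0 + d degrees of freedom (capped at 1e6
when d0 is infinite). Differentially methylated CpGs (DMCs) are probes with
Benjamini-Hochberg FDR below the threshold (default 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .cohort_stats import benjamini_hochberg

MAX_T_DF = 1e6


@dataclass
class ModerationParams:
    """Empirical-Bayes prior: d0 (prior df, may be inf) and s0^2 (prior variance)."""

    d0: float
    s0_sq: float
    d: float  # residual df the prior was fitted against

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be > 0")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be > 0")


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    trigamma is strictly decreasing on (0, inf) with range (0, inf), so the
    solution is unique. Newton on x with analytic derivative (the
    tetragamma function); monotone bisection fallback guards the rare
    overshoot.
    """
    if y <= 0:
        raise ValueError("trigamma is positive; y must be > 0")
    # asymptotics: trigamma(x) ~ 1/x + 1/(2x^2) for large x, ~ 1/x^2 near 0
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        f = float(special.polygamma(1, x)) - y
        if abs(f) < tol * y:
            return x
        fprime = float(special.polygamma(2, x))
        step = f / fprime
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2 if f < 0 else x * 2  # decreasing fn: f<0 => x too big
        x = x_new
    return x


def fit_moderation(sample_variances, d: float) -> ModerationParams:
    """Method-of-moments fit of the variance prior from per-probe variances.

    Under the hierarchical model, e_g = log(s_g^2) - psi(d/2) + log(d/2)
    has mean log(s0^2) + psi(d0/2) - log(d0/2) and variance
    psi'(d0/2) + psi'(d/2); matching moments gives d0 and s0^2. Probes with
    zero variance carry no information about the spread of log-variances
    and are excluded from the fit.
    """
    s2 = np.asarray(sample_variances, dtype=float)
    s2 = s2[np.isfinite(s2)]
    if len(s2) < 10:
        raise ValueError("moderation fit needs >= 10 probe variances")
    if d < 1:
        raise ValueError("residual df must be >= 1")
    positive = s2[s2 > 0]
    if len(positive) == 0:
        raise ValueError("all sample variances are zero")
    e = np.log(positive) - special.digamma(d / 2) + math.log(d / 2)
    mean_e = float(e.mean())
    var_e = float(e.var(ddof=1)) if len(e) > 1 else 0.0
    trigamma_d = float(special.polygamma(1, d / 2))
    if var_e <= trigamma_d:
        # no excess spread: infinite prior df. The prior variance is the
        # geometric mean of the observed variances so the degenerate
        # equal-variance limit returns the common variance exactly.
        return ModerationParams(
            d0=math.inf, s0_sq=float(np.exp(np.mean(np.log(positive)))), d=float(d)
        )
    x = trigamma_inverse(max(var_e - trigamma_d, 1e-8))
    d0 = 2 * x
    s0_sq = math.exp(mean_e + float(special.digamma(d0 / 2)) - math.log(d0 / 2))
    return ModerationParams(d0=d0, s0_sq=s0_sq, d=float(d))


def moderated_t_test(
    mvalues: pd.DataFrame,
    groups: pd.Series,
    params: ModerationParams | None = None,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-probe moderated t-test between two groups of samples.

    ``mvalues`` is probes x samples; ``groups`` maps sample ID to one of
    exactly two labels. Probes with missing values use complete-case group
    means with per-probe df adjustment. When ``params`` is None the variance
    prior is fitted from this matrix (probes at full df).

    Returns a DataFrame indexed by probe with columns ``mean_diff``
    (group1 - group2, in the sorted label order), ``pooled_sd``,
    ``moderated_t``, ``p``, ``fdr``, ``df_total``, ``is_dmc``.
    """
    groups = pd.Series(groups).reindex(mvalues.columns).dropna()
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two group labels, got {labels}")
    g1 = groups.index[groups == labels[0]]
    g2 = groups.index[groups == labels[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("both groups need >= 2 samples")

    x1 = mvalues[g1].to_numpy(dtype=float)
    x2 = mvalues[g2].to_numpy(dtype=float)
    n1 = np.sum(~np.isnan(x1), axis=1)
    n2 = np.sum(~np.isnan(x2), axis=1)
    with np.errstate(invalid="ignore"):
        m1 = np.nanmean(x1, axis=1)
        m2 = np.nanmean(x2, axis=1)
        ss1 = np.nansum((x1 - m1[:, None]) ** 2, axis=1)
        ss2 = np.nansum((x2 - m2[:, None]) ** 2, axis=1)
    d_probe = n1 + n2 - 2
    valid = (n1 >= 2) & (n2 >= 2) & (d_probe >= 1)
    s2 = np.full(len(mvalues), np.nan)
    s2[valid] = (ss1[valid] + ss2[valid]) / d_probe[valid]

    if params is None:
        d_fit = float(np.median(d_probe[valid]))
        params = fit_moderation(s2[valid], d_fit)

    d0 = params.d0
    diff = m1 - m2
    if math.isinf(d0):
        s2_post = np.full_like(s2, params.s0_sq)
        df_total = np.full_like(s2, MAX_T_DF)
    else:
        s2_post = (d0 * params.s0_sq + d_probe * s2) / (d0 + d_probe)
        df_total = np.minimum(d0 + d_probe, MAX_T_DF)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    p = 2 * stats.t.sf(np.abs(t), df_total)
    p = np.where(valid, p, np.nan)

    out = pd.DataFrame(
        {
            "mean_diff": diff,
            "pooled_sd": np.sqrt(s2),
            "moderated_t": np.where(valid, t, np.nan),
            "p": p,
            "df_total": df_total,
        },
        index=mvalues.index,
    )
    out["fdr"] = np.nan
    tested = out.index[out["p"].notna()]
    out.loc[tested, "fdr"] = benjamini_hochberg(out.loc[tested, "p"].to_numpy())
    out["is_dmc"] = out["fdr"] < fdr_threshold
    out.attrs["d0"] = params.d0
    out.attrs["s0_sq"] = params.s0_sq
    out.attrs["group_order"] = labels
    return out


def call_dmcs(
    beta_matrix,
    groups: pd.Series,
    fdr_threshold: float = 0.05,
    epsilon: float = 1e-3,
) -> pd.DataFrame:
    """Convenience wrapper: beta matrix -> M-values -> moderated t -> DMC table."""
    from .preprocess import mvalue_transform

    m = mvalue_transform(beta_matrix, epsilon=epsilon)
    return moderated_t_test(m, groups, fdr_threshold=fdr_threshold)
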