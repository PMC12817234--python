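"""The cohort-level inferential toolbox.

Nonparametric group comparison (two-sided Mann-Whitney U, exact by
enumeration at small sample sizes), Benjamini-Hochberg FDR adjustment,
partial Pearson correlation controlling for a covariate (chronological
age throughout this package), regression-residual association outliers,
median stratification into High/Low groups, one-way ANOVA, a
mutation-screen wrapper, and survival analysis (Kaplan-Meier product-limit
estimator and the two-group log-rank test).

Survival machinery is implemented directly (and cross-checked against
`lifelines` in the test suite) so that every number the pipeline reports
is reproducible from this module alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

EXACT_MW_MAX_N = 12


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a: #(a_i > b_j) + 0.5 * #(a_i == b_j)."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney(a, b, exact_max_n: int = EXACT_MW_MAX_N) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    For pooled sample sizes up to ``exact_max_n`` the p-value is exact: all
    group assignments of the pooled values are enumerated and the two-sided
    p is the fraction whose U is at least as far from n1*n2/2 as the
    observed U (ties handled naturally by the enumeration). Above the
    threshold a normal approximation with midrank tie correction and 0.5
    continuity correction is used.

    Returns ``(U, p)`` where U is the statistic of the first group.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    u = _u_statistic(a, b)
    if n1 + n2 <= exact_max_n:
        pooled = np.concatenate([a, b])
        mid = n1 * n2 / 2.0
        dev = abs(u - mid)
        count = 0
        total = 0
        for idx in combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(idx)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_perm - mid) >= dev - 1e-12:
                count += 1
        return u, count / total
    # normal approximation with tie and continuity correction
    n = n1 + n2
    pooled = np.concatenate([a, b])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    mu = n1 * n2 / 2.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return u, 1.0  # all values tied
    z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(sigma2)
    return u, float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH-adjusted p-values: q_(i) = min_{j >= i} p_(j) * m / j, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Partial Pearson correlation
# ---------------------------------------------------------------------------


def partial_pearson(x, y, control) -> float:
    """First-order partial correlation of x and y controlling for a covariate.

    Computed as the Pearson correlation of the residuals of simple linear
    regressions of x on control and y on control; algebraically equal to
    (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(control, dtype=float)
    if len(x) < 4:
        raise ValueError("partial correlation needs >= 4 observations")

    def residuals(v):
        if np.ptp(z) == 0:
            return v - v.mean()
        slope, intercept = np.polyfit(z, v, 1)
        return v - (intercept + slope * z)

    rx, ry = residuals(x), residuals(y)
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("zero residual variance: input collinear with control")
    return float(np.corrcoef(rx, ry)[0, 1])


# ---------------------------------------------------------------------------
# Association outliers
# ---------------------------------------------------------------------------


@dataclass
class AssocOutlierConfig:
    sd_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if self.sd_multiplier <= 0:
            raise ValueError("sd_multiplier must be > 0")


def association_outliers(
    x: pd.Series, y: pd.Series, config: AssocOutlierConfig | None = None
) -> pd.Index:
    """Observations whose residual from the least-squares line y ~ x exceeds
    ``sd_multiplier`` times the residual standard deviation."""
    config = config or AssocOutlierConfig()
    x = pd.Series(x).astype(float)
    y = pd.Series(y).astype(float).reindex(x.index)
    if len(x) < 3:
        raise ValueError("association outlier detection needs >= 3 observations")
    if np.ptp(x.to_numpy()) == 0:
        raise ValueError("constant x: regression undefined")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    sd = float(resid.std(ddof=1))
    # perfectly linear data: residuals are float roundoff, nothing to flag
    if sd <= 1e-10 * max(1.0, float(np.abs(y).max())):
        return pd.Index([])
    return x.index[np.abs(resid) > config.sd_multiplier * sd]


# ---------------------------------------------------------------------------
# Median stratification
# ---------------------------------------------------------------------------


def median_stratify(values: pd.Series) -> pd.Series:
    """High/Low labels by the median; values equal to the median go to Low
    (deterministic tie rule)."""
    values = pd.Series(values).astype(float)
    if len(values) < 2:
        raise ValueError("median stratification needs >= 2 values")
    med = float(values.median())
    return pd.Series(np.where(values > med, "High", "Low"), index=values.index)


# ---------------------------------------------------------------------------
# One-way ANOVA
# ---------------------------------------------------------------------------


def one_way_anova(groups: list) -> tuple[float, float]:
    """Classical one-way ANOVA F test across >= 2 groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) < 2 for g in arrays):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    all_vals = np.concatenate(arrays)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    df_between = len(arrays) - 1
    df_within = len(all_vals) - len(arrays)
    if ss_within == 0:
        raise ValueError("zero within-group variance everywhere")
    f = (ss_between / df_between) / (ss_within / df_within)
    return float(f), float(stats.f.sf(f, df_between, df_within))


# ---------------------------------------------------------------------------
# Mutation screen
# ---------------------------------------------------------------------------


@dataclass
class MutationScreenConfig:
    """Carrier filters for the per-gene screen: genes with fewer than
    ``min_carriers`` carriers are screened out; ``min_recurrent`` is the
    stricter recurrence filter used for the survival-oriented subset."""

    min_carriers: int = 3
    min_recurrent: int = 11

    def __post_init__(self) -> None:
        if self.min_carriers < 1:
            raise ValueError("min_carriers must be >= 1")


def mutation_screen(
    cohort,
    values: pd.Series,
    config: MutationScreenConfig | None = None,
) -> pd.DataFrame:
    """Mann-Whitney screen of carriers vs non-carriers per mutated gene.

    ``cohort`` is a :class:`~methylaging.io_formats.CohortTable` whose
    ``<gene>_mut`` columns define carrier status; ``values`` is the
    per-sample EA/EAA (or any score). Genes with fewer than ``min_carriers``
    carriers are reported as screened out and excluded from the BH family.
    """
    config = config or MutationScreenConfig()
    values = values.reindex(cohort.table.index).dropna()
    rows = []
    for gene in cohort.mutation_genes():
        flags = cohort.table.loc[values.index, f"{gene}_mut"]
        carriers = values[flags == 1]
        non = values[flags == 0]
        row = {
            "gene": gene,
            "n_carriers": len(carriers),
            "n_noncarriers": len(non),
        }
        if len(carriers) < config.min_carriers:
            row.update(screened_out=True, U=np.nan, p=np.nan)
        else:
            u, p = mann_whitney(carriers.to_numpy(), non.to_numpy())
            row.update(
                screened_out=False,
                U=u,
                p=p,
                median_diff=float(carriers.median() - non.median()),
            )
        rows.append(row)
    out = pd.DataFrame(rows).set_index("gene")
    tested = out.index[~out["screened_out"]]
    out["adj_p"] = np.nan
    if len(tested):
        out.loc[tested, "adj_p"] = benjamini_hochberg(out.loc[tested, "p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Survival: Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimator.

    Returns one row per distinct event time with columns ``time``,
    ``n_at_risk``, ``n_events``, ``n_censored`` (censorings in [previous
    event time, this one)) and ``survival`` = prod (1 - d_i / n_i).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if np.any(t < 0):
        raise ValueError("negative survival time")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("events must be 0 or 1")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    n = len(t)
    rows = []
    surv = 1.0
    for et in event_times:
        at_risk = int(np.sum(t >= et))
        d = int(np.sum((t == et) & (e == 1)))
        c = int(np.sum((t == et) & (e == 0)))
        surv *= 1.0 - d / at_risk
        rows.append(
            {
                "time": float(et),
                "n_at_risk": at_risk,
                "n_events": d,
                "n_censored": c,
                "survival": surv,
            }
        )
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "n_censored", "survival"])


def km_survival_at(km: pd.DataFrame, t: float) -> float:
    """Step-function evaluation of a KM table at time t."""
    past = km[km["time"] <= t]
    return 1.0 if past.empty else float(past["survival"].iloc[-1])


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test.

    At each distinct event time the observed events in group A are compared
    with the expectation under the pooled risk set (hypergeometric mean and
    variance); chi-square = (sum O - sum E)^2 / sum V on 1 df.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    all_times = np.concatenate([ta, tb])
    all_events = np.concatenate([ea, eb])
    if all_events.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    event_times = np.unique(all_times[all_events == 1])
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        n1 = int(np.sum(ta >= et))
        n2 = int(np.sum(tb >= et))
        nj = n1 + n2
        d1 = int(np.sum((ta == et) & (ea == 1)))
        d2 = int(np.sum((tb == et) & (eb == 1)))
        dj = d1 + d2
        if nj == 0 or n1 == 0 and n2 == 0:
            continue
        e1 = dj * n1 / nj
        o_minus_e += d1 - e1
        if nj > 1:
            var += dj * (n1 / nj) * (n2 / nj) * (nj - dj) / (nj - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, 1))


def truncate_followup(times, events, horizon: float) -> tuple[np.ndarray, np.ndarray]:
    """Administrative censoring at a follow-up horizon (e.g. 18 months):
    observations beyond the horizon are censored there."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    beyond = t > horizon
    return np.where(beyond, horizon, t), np.where(beyond, 0, e)
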