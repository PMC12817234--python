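"""Cohort QC and normalization.

Three stages:

* :func:`pca_outlier_filter` — iterative removal of cohort outliers by
  z-scoring each sample's squared distance from the cohort mean along the
  first principal component, converting to one-sided normal p-values,
  Benjamini-Hochberg adjusting, and dropping samples below the FDR
  threshold; repeated until the z-scores fall inside a configured range or
  no sample is removed.
* :func:`bmiq_normalize` — beta-mixture quantile normalization of one
  sample's beta vector onto a reference vector, fitting a three-state
  (unmethylated / hemimethylated / methylated) beta mixture to each by EM
  and mapping state-conditional quantiles of the sample onto the reference.
  Required for pan-tissue-style clocks; causality-enriched clocks consume
  raw betas.
* :func:`mvalue_transform` — the variance-stabilizing logit2 transform used
  for differential testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betainc

from .cohort_stats import benjamini_hochberg
from .io_formats import BetaMatrix

# ---------------------------------------------------------------------------
# PCA outlier filter
# ---------------------------------------------------------------------------


@dataclass
class OutlierFilterConfig:
    fdr_threshold: float = 0.2
    z_range: tuple[float, float] = (-20.0, 20.0)
    max_iterations: int = 20

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.z_range[0] != -self.z_range[1]:
            raise ValueError("z_range must be symmetric about 0")


@dataclass
class OutlierFilterReport:
    removed_per_iteration: list[list[str]]
    final_z: pd.Series
    iterations: int
    status: str  # "no_removals" | "z_in_range" | "max_iterations" | "zero_variance" | "too_few_samples"
    stopping_quantity: str = "z_score"

    @property
    def removed(self) -> list[str]:
        return [s for it in self.removed_per_iteration for s in it]


def _pc1_squared_distance(values: pd.DataFrame) -> np.ndarray | None:
    """Squared distance of each sample from the cohort mean along PC1.

    Probes are mean-centered (no scaling: betas share the [0, 1] scale);
    samples are projected onto the first principal component. Returns None
    when there is no variance along PC1.
    """
    x = values.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    # economy SVD of probes x samples; sample PC1 coords = s[0] * vt[0]
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    if s[0] <= 1e-12:
        return None
    coords = s[0] * vt[0]
    return (coords - coords.mean()) ** 2


def pca_outlier_filter(
    matrix: BetaMatrix, config: OutlierFilterConfig | None = None
) -> tuple[BetaMatrix, OutlierFilterReport]:
    """Iteratively remove cohort outliers along the first principal component.

    Per iteration: (1) PC1 of the probe-centered matrix; (2) squared
    distance d2_i of each sample from the mean along PC1; (3) z_i =
    (d2_i - mean d2) / sd d2; (4) one-sided p_i = 1 - Phi(z_i) (only large
    distances indicate outliers); (5) Benjamini-Hochberg; (6) remove samples
    with adjusted p below the FDR threshold. Iteration stops when no sample
    is removed, when all remaining z-scores lie inside ``z_range``, or at
    ``max_iterations``.
    """
    config = config or OutlierFilterConfig()
    values = matrix.values.dropna(axis=0, how="any")
    if matrix.shape[1] < 3:
        raise ValueError("outlier filter needs at least 3 samples")

    kept = values
    removed_per_iter: list[list[str]] = []
    status = "max_iterations"
    final_z = pd.Series(0.0, index=kept.columns)
    iterations = 0
    for _ in range(config.max_iterations):
        iterations += 1
        d2 = _pc1_squared_distance(kept)
        if d2 is None:
            status = "zero_variance"
            final_z = pd.Series(0.0, index=kept.columns)
            break
        sd = d2.std(ddof=1)
        if sd <= 1e-300:
            status = "zero_variance"
            final_z = pd.Series(0.0, index=kept.columns)
            break
        z = (d2 - d2.mean()) / sd
        final_z = pd.Series(z, index=kept.columns)
        p = 1.0 - stats.norm.cdf(z)
        q = benjamini_hochberg(p)
        flagged = list(kept.columns[q < config.fdr_threshold])
        if not flagged:
            status = "no_removals"
            break
        removed_per_iter.append(flagged)
        kept = kept.drop(columns=flagged)
        if kept.shape[1] < 3:
            status = "too_few_samples"
            final_z = pd.Series(dtype=float)
            break
        d2 = _pc1_squared_distance(kept)
        if d2 is not None and d2.std(ddof=1) > 1e-300:
            z_next = (d2 - d2.mean()) / d2.std(ddof=1)
            final_z = pd.Series(z_next, index=kept.columns)
            if np.all((z_next >= config.z_range[0]) & (z_next <= config.z_range[1])):
                status = "z_in_range"
                break

    report = OutlierFilterReport(
        removed_per_iteration=removed_per_iter,
        final_z=final_z,
        iterations=iterations,
        status=status,
    )
    kept_matrix = matrix.subset_samples(kept.columns)
    return kept_matrix, report


# ---------------------------------------------------------------------------
# BMIQ-style beta-mixture quantile normalization
# ---------------------------------------------------------------------------


class EMConvergenceError(RuntimeError):
    def __init__(self, trace: list[float]):
        super().__init__(
            f"beta-mixture EM did not converge after {len(trace)} iterations"
        )
        self.trace = trace


@dataclass
class BetaMixture:
    """Three-state beta mixture: unmethylated / hemimethylated / methylated."""

    weights: np.ndarray  # (3,)
    a: np.ndarray  # (3,) shape parameters
    b: np.ndarray

    def state_boundaries(self) -> tuple[float, float]:
        """Crossover points between adjacent state densities on a grid."""
        grid = np.linspace(1e-4, 1 - 1e-4, 2001)
        dens = np.stack(
            [w * stats.beta.pdf(grid, ai, bi) for w, ai, bi in zip(self.weights, self.a, self.b)]
        )
        assign = np.argmax(dens, axis=0)
        t1 = grid[np.searchsorted(assign, 1)] if np.any(assign >= 1) else 0.5
        t2 = grid[np.searchsorted(assign, 2)] if np.any(assign == 2) else max(0.8, t1 + 0.1)
        return float(t1), float(max(t2, t1 + 1e-3))


def _weighted_beta_mom(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted method-of-moments estimate of Beta(a, b) parameters."""
    wsum = w.sum()
    m = float((w * x).sum() / wsum)
    v = float((w * (x - m) ** 2).sum() / wsum)
    m = min(max(m, 1e-4), 1 - 1e-4)
    v = max(v, 1e-8)
    common = m * (1 - m) / v - 1
    common = max(common, 1e-3)
    return max(m * common, 1e-2), max((1 - m) * common, 1e-2)


def fit_beta_mixture(
    betas: np.ndarray,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> BetaMixture:
    """Fit a three-state beta mixture by EM with M-step by weighted moments.

    States are initialized by beta-value thresholds (<= 0.2 unmethylated,
    0.2-0.8 hemimethylated, >= 0.8 methylated); EM stops when the mean
    log-likelihood changes by less than ``tol``.
    """
    x = np.clip(np.asarray(betas, dtype=float), 1e-4, 1 - 1e-4)
    resp = np.zeros((3, len(x)))
    resp[0] = x <= 0.2
    resp[1] = (x > 0.2) & (x < 0.8)
    resp[2] = x >= 0.8
    resp += 1e-3  # keep every state alive
    resp /= resp.sum(axis=0, keepdims=True)

    weights = resp.mean(axis=1)
    a = np.empty(3)
    b = np.empty(3)
    for k in range(3):
        a[k], b[k] = _weighted_beta_mom(x, resp[k])

    trace: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        dens = np.stack([weights[k] * stats.beta.pdf(x, a[k], b[k]) for k in range(3)])
        total = dens.sum(axis=0)
        total = np.maximum(total, 1e-300)
        ll = float(np.mean(np.log(total)))
        trace.append(ll)
        resp = dens / total
        weights = np.maximum(resp.mean(axis=1), 1e-6)
        weights /= weights.sum()
        for k in range(3):
            a[k], b[k] = _weighted_beta_mom(x, resp[k])
        if abs(ll - prev_ll) < tol:
            return BetaMixture(weights, a, b)
        prev_ll = ll
    raise EMConvergenceError(trace)


def _truncated_quantile_map(
    x: np.ndarray,
    samp: tuple[float, float],
    ref: tuple[float, float],
    lo_s: float,
    hi_s: float,
    lo_r: float,
    hi_r: float,
) -> np.ndarray:
    """Map x in [lo_s, hi_s] onto [lo_r, hi_r] via truncated beta CDFs.

    ``samp``/``ref`` are (a, b) shape pairs of the matching state in the
    sample and reference mixtures. Boundaries map to boundaries, so
    composing per-state maps yields a continuous monotone transform.
    """
    a_s, b_s = samp
    a_r, b_r = ref
    f_lo, f_hi = betainc(a_s, b_s, lo_s), betainc(a_s, b_s, hi_s)
    span = max(f_hi - f_lo, 1e-12)
    p = (betainc(a_s, b_s, np.clip(x, lo_s, hi_s)) - f_lo) / span
    p = np.clip(p, 0.0, 1.0)
    g_lo, g_hi = betainc(a_r, b_r, lo_r), betainc(a_r, b_r, hi_r)
    target = g_lo + p * (g_hi - g_lo)
    y = stats.beta.ppf(np.clip(target, 1e-12, 1 - 1e-12), a_r, b_r)
    return np.clip(y, lo_r, hi_r)


def bmiq_normalize(
    sample: pd.Series,
    reference: pd.Series,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> pd.Series:
    """Normalize one beta vector onto a reference by beta-mixture quantile mapping.

    Both vectors must cover the same probes. A three-state beta mixture is
    fitted to each; the beta axis is partitioned at the sample's state
    crossover points, and each partition is mapped onto the corresponding
    reference partition through truncated state-conditional beta CDFs
    (hemimethylated values are interpolated linearly between the anchors).
    The transform is continuous and monotone, so within-sample rank order is
    preserved; output stays in [0, 1].
    """
    if not sample.index.equals(reference.index):
        reference = reference.reindex(sample.index)
        if reference.isna().any():
            raise ValueError("sample and reference must cover the same probes")
    x = np.clip(sample.to_numpy(dtype=float), 1e-4, 1 - 1e-4)
    r = np.clip(reference.to_numpy(dtype=float), 1e-4, 1 - 1e-4)

    mix_s = fit_beta_mixture(x, tol=tol, max_iter=max_iter)
    mix_r = fit_beta_mixture(r, tol=tol, max_iter=max_iter)
    t1_s, t2_s = mix_s.state_boundaries()
    t1_r, t2_r = mix_r.state_boundaries()

    out = np.empty_like(x)
    lo = x <= t1_s
    hi = x >= t2_s
    mid = ~lo & ~hi
    out[lo] = _truncated_quantile_map(
        x[lo], (mix_s.a[0], mix_s.b[0]), (mix_r.a[0], mix_r.b[0]), 1e-4, t1_s, 1e-4, t1_r
    )
    out[hi] = _truncated_quantile_map(
        x[hi], (mix_s.a[2], mix_s.b[2]), (mix_r.a[2], mix_r.b[2]), t2_s, 1 - 1e-4, t2_r, 1 - 1e-4
    )
    # hemimethylated state: linear bridge between the two anchor points
    if np.any(mid):
        out[mid] = t1_r + (x[mid] - t1_s) * (t2_r - t1_r) / (t2_s - t1_s)
    return pd.Series(np.clip(out, 0.0, 1.0), index=sample.index)


def bmiq_normalize_matrix(matrix: BetaMatrix, reference: pd.Series | None = None) -> BetaMatrix:
    """Apply :func:`bmiq_normalize` to every sample of a matrix.

    The default reference is the probe-wise median sample of the cohort, a
    deterministic cohort-internal choice.
    """
    if reference is None:
        reference = matrix.values.median(axis=1, skipna=True)
    out = {
        s: bmiq_normalize(matrix.values[s], reference) for s in matrix.sample_ids
    }
    return BetaMatrix(pd.DataFrame(out, index=matrix.values.index))


# ---------------------------------------------------------------------------
# M-value transform
# ---------------------------------------------------------------------------


def mvalue_transform(matrix: BetaMatrix, epsilon: float = 1e-3) -> pd.DataFrame:
    """Logit2 transform: M = log2(beta' / (1 - beta')), beta' clipped to
    [epsilon, 1 - epsilon]."""
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    b = matrix.values.clip(lower=epsilon, upper=1 - epsilon)
    return np.log2(b / (1 - b))


def mvalue_inverse(m: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`mvalue_transform` (recovers the clipped beta)."""
    return 2**m / (1 + 2**m)
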