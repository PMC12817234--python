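"""Transcription-factor enrichment of differentially methylated CpGs.

For each TF, the CpG probes overlapping its ChIP-seq binding regions are
tested for over-representation among the DMCs with an upper-tail
hypergeometric test against the genome-wide background of measured probes:
p = P(X >= k) with X ~ Hypergeometric(N, K, n), where N is the universe
size, K the universe probes in the TF's regions, n the DMC count and k the
DMC/TF overlap. TFs with fewer than ``min_overlap_cpgs`` universe CpGs in
their regions are excluded before FDR control to avoid spurious hits from
tiny annotation sets; BH runs over the tested TFs only.

The module also ranks TFs by the partial Pearson correlation (controlling
chronological age) between per-sample mean methylation at their binding
sites and epigenetic age — the analysis that singles out the PRC2 core
subunits EZH2 and SUZ12 in AML cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_stats import benjamini_hochberg, partial_pearson


@dataclass
class EnrichmentConfig:
    min_overlap_cpgs: int = 5
    fdr_threshold: float = 0.05
    # "fewer than five overlapping CpGs" read as K < 5 (universe overlap);
    # set to "dmc" to exclude on k < 5 instead.
    exclusion_basis: str = "universe"

    def __post_init__(self) -> None:
        if self.min_overlap_cpgs < 1:
            raise ValueError("min_overlap_cpgs must be >= 1")
        if self.exclusion_basis not in ("universe", "dmc"):
            raise ValueError("exclusion_basis must be 'universe' or 'dmc'")


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def tf_enrichment(
    dmc: set[str],
    tf_probe_sets: Mapping[str, set[str]],
    universe: set[str],
    config: EnrichmentConfig | None = None,
) -> pd.DataFrame:
    """Hypergeometric DMC enrichment per TF with BH control.

    Returns a DataFrame indexed by TF with columns ``k`` (DMCs in TF
    regions), ``K`` (universe CpGs in TF regions), ``n`` (|DMC|), ``N``
    (|universe|), ``p``, ``fdr``, ``excluded``, ``significant``. Excluded
    TFs (overlap below ``min_overlap_cpgs``) do not enter the BH family.
    """
    config = config or EnrichmentConfig()
    if not universe:
        raise ValueError("empty probe universe")
    dmc = set(dmc) & set(universe)
    if not dmc:
        raise ValueError("empty DMC set (after intersecting with universe)")
    N, n = len(universe), len(dmc)
    rows = []
    for tf, probes in tf_probe_sets.items():
        tf_in_universe = set(probes) & set(universe)
        K = len(tf_in_universe)
        k = len(tf_in_universe & dmc)
        basis = K if config.exclusion_basis == "universe" else k
        excluded = basis < config.min_overlap_cpgs
        rows.append(
            {
                "tf": tf,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": np.nan if excluded else hypergeom_upper_tail(k, N, K, n),
                "excluded": excluded,
            }
        )
    out = pd.DataFrame(rows).set_index("tf")
    tested = out.index[~out["excluded"]]
    out["fdr"] = np.nan
    if len(tested):
        out.loc[tested, "fdr"] = benjamini_hochberg(out.loc[tested, "p"].to_numpy())
    out["significant"] = out["fdr"] < config.fdr_threshold
    return out.sort_values(["fdr", "p"], na_position="last")


def ea_tf_methylation_correlation(
    tf_scores: pd.DataFrame,
    epigenetic_age: pd.Series,
    chronological_age: pd.Series,
    top_k: int = 20,
) -> pd.DataFrame:
    """Partial correlation (controlling chronological age) between per-TF
    binding-site methylation and epigenetic age, ranked by |r|.

    ``tf_scores`` is samples x TFs (mean beta at each TF's binding-site
    CpGs). TFs whose score vector is constant have no defined correlation
    and are reported with NaN, excluded from the ranking.
    """
    samples = tf_scores.index.intersection(epigenetic_age.index).intersection(
        chronological_age.index
    )
    if len(samples) < 4:
        raise ValueError("partial correlation needs >= 4 samples")
    ea = epigenetic_age.loc[samples].to_numpy(dtype=float)
    age = chronological_age.loc[samples].to_numpy(dtype=float)
    rows = []
    for tf in tf_scores.columns:
        score = tf_scores.loc[samples, tf].to_numpy(dtype=float)
        try:
            r = partial_pearson(score, ea, age)
        except ValueError:
            r = np.nan
        rows.append({"tf": tf, "partial_r": r, "n": len(samples)})
    out = pd.DataFrame(rows).set_index("tf")
    out["abs_r"] = out["partial_r"].abs()
    out["rank"] = out["abs_r"].rank(ascending=False, method="first", na_option="bottom")
    out = out.sort_values("rank")
    out["top_k"] = out["rank"] <= top_k
    return out
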