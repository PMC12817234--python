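"""Genomic-interval engine for PRC2-target analysis.

Implements the region operations the pipeline needs: base-wise intersection
of ChIP-seq peak sets (PRC2 targets = EZH2 peaks intersected with SUZ12
peaks), TSS / non-TSS annotation, promoter windows, probe-to-region mapping,
per-sample region methylation scores (the mean beta over member CpGs, i.e.
PRC2m when applied to PRC2 targets), and the stratification of PRC2-bound
low-methylated regions (LMCs) into equal-size age groups.

All intervals are 0-based half-open and sorted by (chrom, start). The
interval algebra is intentionally small and is validated in the test suite
against per-base brute-force oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd


class Interval(NamedTuple):
    chrom: str
    start: int
    end: int
    score: float
    name: str | None


@dataclass
class RegionSet:
    """A sorted set of 0-based half-open genomic intervals with optional scores."""

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    scores: np.ndarray | None = None
    names: np.ndarray | None = None

    @classmethod
    def from_arrays(cls, chroms, starts, ends, scores=None, names=None) -> "RegionSet":
        chroms = np.asarray(chroms, dtype=object)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if np.any(starts >= ends):
            i = int(np.argmax(starts >= ends))
            raise ValueError(f"interval start >= end: {chroms[i]}:{starts[i]}-{ends[i]}")
        order = np.lexsort((starts, chroms.astype(str)))
        scores = None if scores is None else np.asarray(scores, dtype=float)[order]
        names = None if names is None else np.asarray(names, dtype=object)[order]
        return cls(chroms[order], starts[order], ends[order], scores, names)

    @classmethod
    def from_tuples(cls, tuples: Sequence[tuple]) -> "RegionSet":
        """Build from (chrom, start, end[, score]) tuples."""
        if not tuples:
            return cls.empty()
        chroms = [t[0] for t in tuples]
        starts = [t[1] for t in tuples]
        ends = [t[2] for t in tuples]
        scores = [t[3] for t in tuples] if len(tuples[0]) > 3 else None
        return cls.from_arrays(chroms, starts, ends, scores=scores)

    @classmethod
    def empty(cls) -> "RegionSet":
        return cls(
            np.empty(0, dtype=object),
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
        )

    def __len__(self) -> int:
        return len(self.starts)

    def __iter__(self) -> Iterator[Interval]:
        for i in range(len(self)):
            yield Interval(
                str(self.chroms[i]),
                int(self.starts[i]),
                int(self.ends[i]),
                float(self.scores[i]) if self.scores is not None else float("nan"),
                str(self.names[i]) if self.names is not None else None,
            )

    def as_tuples(self) -> list[tuple[str, int, int]]:
        return [(str(c), int(s), int(e)) for c, s, e in zip(self.chroms, self.starts, self.ends)]

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in pd.unique(self.chroms.astype(str)):
            mask = self.chroms.astype(str) == chrom
            out[chrom] = (self.starts[mask], self.ends[mask])
        return out

    def total_bases(self) -> int:
        return int(np.sum(self.ends - self.starts))


def intersect_region_sets(a: RegionSet, b: RegionSet) -> RegionSet:
    """Base-wise intersection of two interval sets.

    Each output fragment is the overlap of one interval from ``a`` with one
    from ``b``; adjacent fragments are not merged.
    """
    out: list[tuple[str, int, int]] = []
    b_by_chrom = b.by_chrom()
    for chrom, (a_starts, a_ends) in a.by_chrom().items():
        if chrom not in b_by_chrom:
            continue
        b_starts, b_ends = b_by_chrom[chrom]
        i = j = 0
        # both sides sorted by start: classic two-pointer sweep
        while i < len(a_starts) and j < len(b_starts):
            lo = max(a_starts[i], b_starts[j])
            hi = min(a_ends[i], b_ends[j])
            if lo < hi:
                out.append((chrom, int(lo), int(hi)))
            if a_ends[i] <= b_ends[j]:
                i += 1
            else:
                j += 1
    if not out:
        return RegionSet.empty()
    return RegionSet.from_tuples(out)


def annotate_tss(regions: RegionSet, tss: Sequence[tuple[str, int]]) -> np.ndarray:
    """Flag each region as TSS (contains >= 1 TSS position) or not.

    TSS coordinates are 0-based positions; a region [start, end) contains a
    TSS at ``pos`` when ``start <= pos < end``.
    """
    tss_by_chrom: dict[str, np.ndarray] = {}
    for chrom, pos in tss:
        tss_by_chrom.setdefault(str(chrom), []).append(int(pos))  # type: ignore[arg-type]
    tss_by_chrom = {c: np.sort(np.asarray(p)) for c, p in tss_by_chrom.items()}
    flags = np.zeros(len(regions), dtype=bool)
    for i in range(len(regions)):
        positions = tss_by_chrom.get(str(regions.chroms[i]))
        if positions is None:
            continue
        k = np.searchsorted(positions, regions.starts[i], side="left")
        flags[i] = k < len(positions) and positions[k] < regions.ends[i]
    return flags


def promoter_windows(
    tss: Sequence[tuple[str, int] | tuple[str, int, str]],
    upstream: int = 3000,
    downstream: int = 200,
) -> RegionSet:
    """Promoter windows around TSS coordinates.

    On "+" the window is [tss - upstream, tss + downstream); on "-" it is
    [tss - downstream, tss + upstream). Strand defaults to "+" when absent;
    windows are clipped at 0.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    tuples = []
    for entry in tss:
        chrom, pos = entry[0], int(entry[1])
        strand = entry[2] if len(entry) > 2 else "+"
        if strand == "-":
            start, end = pos - downstream, pos + upstream
        else:
            start, end = pos - upstream, pos + downstream
        tuples.append((chrom, max(0, start), max(1, end)))
    return RegionSet.from_tuples(tuples)


def map_probes(manifest, regions: RegionSet) -> dict[str, list[int]]:
    """Map each probe to the indices of every region containing its position.

    ``manifest`` is an :class:`~methylaging.io_formats.ProbeManifest` (1-based
    positions); a probe at 1-based ``pos`` falls in [start, end) when
    ``start <= pos - 1 < end``. Probes hitting no region are omitted.
    """
    region_by_chrom: dict[str, list[int]] = {}
    for i in range(len(regions)):
        region_by_chrom.setdefault(str(regions.chroms[i]), []).append(i)
    membership: dict[str, list[int]] = {}
    table = manifest.table
    for probe_id, chrom, pos in zip(table.index, table["chrom"], table["pos"]):
        p0 = int(pos) - 1
        hits = [
            i
            for i in region_by_chrom.get(str(chrom), [])
            if regions.starts[i] <= p0 < regions.ends[i]
        ]
        if hits:
            membership[str(probe_id)] = hits
    return membership


def region_methylation_score(
    matrix, membership: Mapping[str, Sequence[int]], set_name: str
) -> pd.DataFrame:
    """Per-sample mean beta over member CpGs of a region set.

    This is the PRC2m statistic when ``membership`` maps probes to PRC2
    binding regions: the unweighted mean of beta values at all CpGs inside
    the set, per sample. Missing betas are excluded per sample and the
    number of CpGs actually used is reported.
    """
    probes = [p for p in membership if p in matrix.values.index]
    if not probes:
        raise ValueError(f"region set {set_name!r} has no member CpGs in the matrix")
    sub = matrix.values.loc[probes]
    return pd.DataFrame(
        {
            "region_set": set_name,
            "mean_beta": sub.mean(axis=0, skipna=True),
            "n_cpgs_used": sub.notna().sum(axis=0),
        }
    )


@dataclass
class LmcStratConfig:
    """Configuration for PRC2-bound low-methylated-region age stratification.

    Samples are split into ``n_groups`` equal-size groups (remainder assigned
    to the highest groups) by chronological or epigenetic age; LMC regions
    (reference mean beta below ``lmc_beta_threshold``) are ranked ascending by
    reference methylation and binned into ``n_region_bins`` equal-count bins.
    """

    n_groups: int = 7
    grouping_variable: str = "epigenetic_age"  # or "chronological_age"
    n_region_bins: int = 5
    lmc_beta_threshold: float = 0.3

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ValueError("n_groups must be >= 2")
        if self.grouping_variable not in ("chronological_age", "epigenetic_age"):
            raise ValueError(f"unknown grouping variable {self.grouping_variable!r}")


def equal_count_groups(values: pd.Series, n_groups: int) -> pd.Series:
    """Assign samples to ``n_groups`` equal-size groups by ascending value.

    Group sizes differ by at most 1; remainder samples go to the highest
    (oldest) groups. Ties are broken by sample ID for determinism.
    """
    order = values.sort_values(kind="mergesort").index
    n = len(order)
    base, rem = divmod(n, n_groups)
    sizes = [base + (1 if g >= n_groups - rem else 0) for g in range(n_groups)]
    labels = np.repeat(np.arange(n_groups), sizes)
    return pd.Series(labels, index=order).reindex(values.index)


def lmc_stratification(
    matrix,
    prc2_membership: Mapping[str, Sequence[int]],
    n_regions: int,
    grouping_values: pd.Series,
    config: LmcStratConfig | None = None,
) -> pd.DataFrame:
    """Mean methylation of LMC region bins across equal-size age groups.

    1. LMC regions = PRC2 regions whose cohort-reference (probe-median over
       samples, mean over region CpGs) methylation is below the threshold.
    2. LMC regions ranked ascending by reference methylation, split into
       equal-count bins.
    3. Samples ranked by ``grouping_values`` (chronological or epigenetic
       age) and split into equal-size groups.
    4. Cell (group, bin) = mean beta over that group's samples and that
       bin's region CpGs.

    Returns a DataFrame indexed by group (0 = youngest) with one column per
    region bin (0 = least methylated).
    """
    config = config or LmcStratConfig()
    # region -> probes
    region_probes: dict[int, list[str]] = {}
    for probe, region_idxs in prc2_membership.items():
        if probe not in matrix.values.index:
            continue
        for r in region_idxs:
            region_probes.setdefault(r, []).append(probe)
    if not region_probes:
        raise ValueError("no PRC2 region has CpGs in the matrix")

    ref_sample = matrix.values.median(axis=1, skipna=True)
    region_ref = {
        r: float(ref_sample.loc[probes].mean()) for r, probes in region_probes.items()
    }
    lmc = sorted(
        (r for r in region_ref if region_ref[r] < config.lmc_beta_threshold),
        key=lambda r: (region_ref[r], r),
    )
    if len(lmc) < config.n_region_bins:
        raise ValueError(
            f"only {len(lmc)} LMC regions below beta {config.lmc_beta_threshold}; "
            f"reduce n_region_bins (= {config.n_region_bins})"
        )

    bin_labels = equal_count_groups(
        pd.Series({r: region_ref[r] for r in lmc}), config.n_region_bins
    )
    groups = equal_count_groups(grouping_values.loc[matrix.sample_ids], config.n_groups)

    cells = np.full((config.n_groups, config.n_region_bins), np.nan)
    for b in range(config.n_region_bins):
        probes = sorted(
            {p for r in bin_labels.index[bin_labels == b] for p in region_probes[r]}
        )
        sub = matrix.values.loc[probes]
        for g in range(config.n_groups):
            samples = groups.index[groups == g]
            cells[g, b] = float(sub.loc[:, samples].to_numpy(dtype=float).mean())
    out = pd.DataFrame(
        cells,
        index=pd.RangeIndex(config.n_groups, name="age_group"),
        columns=pd.RangeIndex(config.n_region_bins, name="region_bin"),
    )
    out.attrs["grouping_variable"] = config.grouping_variable
    out.attrs["n_lmc_regions"] = len(lmc)
    return out
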