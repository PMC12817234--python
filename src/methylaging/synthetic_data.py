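"""Seeded synthetic 450K-style cohorts with planted, recoverable structure.

The generator emulates the statistical structure of a leukemia methylation
study cohort and its companion resources — a probes x samples beta matrix,
clinical annotation with mutation flags and survival, a probe manifest,
ChIP-seq-style peak files for a panel of TFs, and linear clock coefficient
files — while planting every effect the downstream stages are built to
detect:

* age-associated CpGs whose beta drifts linearly with a latent biological
  age (chronological age plus Normal jitter, so that adaptive-score
  stratification can outperform chronological stratification);
* PRC2-bound low-methylated regions that start near a low baseline and
  gain methylation with biological age, covered by co-occurring EZH2-like
  and SUZ12-like peaks;
* mutation groups whose PRC2-region methylation is shifted down
  (DNMT3A-like) or up (IDH2-like) — these region CpGs are the planted DMCs;
* whole-sample outliers with a global mean-beta shift;
* survival times drawn from exponential hazards that differ between the
  High and Low halves of the planted adaptive (biological-age) score.

Every planted entity is reported in :class:`SyntheticTruth` so recovery
tests can score the pipeline against ground truth. Identical seeds yield
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    BetaMatrix,
    ClockDefinition,
    CohortTable,
    ProbeManifest,
    write_bed,
    write_beta_matrix,
    write_clinical,
    write_clock,
    write_json,
    write_manifest,
)
from .regions import RegionSet


class ConfigError(ValueError):
    """Raised when a synthetic cohort configuration is internally inconsistent."""


@dataclass
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a mid-sized leukemia-like cohort on a down-sampled
    array: 200 samples, 5000 probes, ages 20-90, ~4% of probes
    age-associated at 0.002 beta-units/year (the magnitude typical of
    blood aging CpGs), 40 PRC2 regions of 8 probes each with low baselines
    and age-related gain, a quarter of samples DNMT3A-like (PRC2
    methylation deficit) and a tenth IDH2-like (excess).
    """

    n_samples: int = 200
    n_probes: int = 5000
    age_range: tuple[float, float] = (20.0, 90.0)
    n_age_cpgs: int = 200
    age_slope: float = 0.002  # beta-units per year of biological age
    n_prc2_regions: int = 40
    probes_per_region: int = 8
    prc2_baseline_beta: float = 0.08
    prc2_baseline_spread: float = 0.12  # region baselines span [base, base+spread]
    prc2_gain_per_unit_bioage: float = 0.002
    mutation_fractions: dict[str, float] = field(
        default_factory=lambda: {"DNMT3A": 0.25, "IDH2": 0.10}
    )
    prc2_mutation_shift: dict[str, float] = field(
        default_factory=lambda: {"DNMT3A": -0.08, "IDH2": 0.06}
    )
    n_decoy_genes: int = 5
    decoy_gene_carrier_fraction: float = 0.10
    n_decoy_tfs: int = 10
    n_outlier_samples: int = 0
    outlier_shift: float = 0.3
    noise_sd: float = 0.02
    bioage_jitter_sd: float = 5.0  # years; latent biological age around chronological
    survival_hazard_ratio_high_vs_low_adapt: float = 2.5
    baseline_median_survival_months: float = 24.0
    censoring_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for label, frac in self.mutation_fractions.items():
            if not 0 <= frac <= 1:
                raise ConfigError(f"mutation fraction for {label!r} outside [0, 1]")
        if sum(self.mutation_fractions.values()) > 1 + 1e-12:
            raise ConfigError("mutation fractions sum to more than 1")
        if not 0 <= self.censoring_rate < 1:
            raise ConfigError("censoring_rate must be in [0, 1)")
        if self.n_probes < self.n_age_cpgs + self.n_prc2_regions * self.probes_per_region:
            raise ConfigError(
                f"n_probes={self.n_probes} too small for {self.n_age_cpgs} age CpGs "
                f"plus {self.n_prc2_regions}x{self.probes_per_region} region probes"
            )
        if self.n_outlier_samples > self.n_samples:
            raise ConfigError("more outlier samples than samples")

    # -- probe layout ------------------------------------------------------

    @property
    def n_region_probes(self) -> int:
        return self.n_prc2_regions * self.probes_per_region

    def age_cpg_ids(self) -> list[str]:
        return [f"cg{i:08d}" for i in range(self.n_age_cpgs)]

    def region_probe_ids(self) -> list[str]:
        lo = self.n_age_cpgs
        return [f"cg{i:08d}" for i in range(lo, lo + self.n_region_probes)]

    def all_probe_ids(self) -> list[str]:
        return [f"cg{i:08d}" for i in range(self.n_probes)]

    def sample_ids(self) -> list[str]:
        return [f"S{i:04d}" for i in range(self.n_samples)]


@dataclass
class SyntheticTruth:
    """Ground truth for everything the generator planted."""

    bioage: pd.Series  # latent biological age per sample, years
    group_labels: pd.Series  # mutation-group label per sample ("WT" = none)
    outlier_samples: list[str]
    dmc_probes: dict[str, list[str]]  # mutation label -> planted DMC probe IDs
    age_cpgs: list[str]
    region_membership: dict[str, int]  # region probe -> region index
    region_baselines: list[float]
    adaptive_group: pd.Series  # High/Low by median latent biological age
    tss_regions: list[int]  # region indices that contain a TSS

    def to_json_dict(self) -> dict:
        return {
            "bioage": self.bioage.round(6).to_dict(),
            "group_labels": self.group_labels.to_dict(),
            "outlier_samples": self.outlier_samples,
            "dmc_probes": self.dmc_probes,
            "age_cpgs": self.age_cpgs,
            "region_membership": self.region_membership,
            "region_baselines": self.region_baselines,
            "adaptive_group": self.adaptive_group.to_dict(),
            "tss_regions": self.tss_regions,
        }


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def draw_survival(
    high_mask: np.ndarray,
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Survival times (months) and event flags for High/Low adaptive groups.

    Event times are exponential with the Low group at the baseline hazard
    (median survival ``baseline_median_survival_months``) and the High group
    at ``survival_hazard_ratio_high_vs_low_adapt`` times that hazard.
    Censoring is an independent exponential clock whose rate is matched to
    the configured expected censoring fraction.
    """
    high_mask = np.asarray(high_mask, dtype=bool)
    n = len(high_mask)
    hr = config.survival_hazard_ratio_high_vs_low_adapt
    lam_low = math.log(2) / config.baseline_median_survival_months
    lam = np.where(high_mask, hr * lam_low, lam_low)
    event_t = rng.exponential(1.0 / lam)
    if config.censoring_rate > 0:
        lam_c = config.censoring_rate / (1 - config.censoring_rate) * lam.mean()
        censor_t = rng.exponential(1.0 / lam_c, size=n)
    else:
        censor_t = np.full(n, np.inf)
    times = np.minimum(event_t, censor_t)
    events = (event_t <= censor_t).astype(int)
    return times, events


def _assign_groups(config: SyntheticCohortConfig, rng: np.random.Generator) -> pd.Series:
    samples = config.sample_ids()
    labels = np.array(["WT"] * config.n_samples, dtype=object)
    perm = rng.permutation(config.n_samples)
    cursor = 0
    for label, frac in config.mutation_fractions.items():
        count = int(round(frac * config.n_samples))
        labels[perm[cursor : cursor + count]] = label
        cursor += count
    return pd.Series(labels, index=samples, name="group")


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[BetaMatrix, CohortTable, SyntheticTruth]:
    """Generate one seeded cohort: beta matrix, clinical table, ground truth."""
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_probes
    samples = config.sample_ids()
    probes = config.all_probe_ids()
    lo_age, hi_age = config.age_range

    age = rng.uniform(lo_age, hi_age, size=n)
    bioage = age + (
        rng.normal(0.0, config.bioage_jitter_sd, size=n)
        if config.bioage_jitter_sd > 0
        else 0.0
    )
    groups = _assign_groups(config, rng)

    betas = np.empty((p, n))
    mid_age = (lo_age + hi_age) / 2.0

    # age CpGs: linear drift with latent biological age around a mid baseline
    n_age = config.n_age_cpgs
    betas[:n_age] = 0.4 + config.age_slope * (bioage - mid_age)[None, :]

    # PRC2 region probes: low baseline per region + gain with biological age
    # + per-group shift (the planted DMCs)
    n_reg = config.n_region_probes
    denom = max(config.n_prc2_regions - 1, 1)
    region_baselines = [
        config.prc2_baseline_beta + config.prc2_baseline_spread * r / denom
        for r in range(config.n_prc2_regions)
    ]
    shift = np.array(
        [config.prc2_mutation_shift.get(g, 0.0) for g in groups.to_numpy()]
    )
    gain = config.prc2_gain_per_unit_bioage * (bioage - lo_age)
    for r in range(config.n_prc2_regions):
        sl = slice(n_age + r * config.probes_per_region, n_age + (r + 1) * config.probes_per_region)
        betas[sl] = region_baselines[r] + gain[None, :] + shift[None, :]

    # background probes: bimodal probe means, constant across samples
    n_bg = p - n_age - n_reg
    low_mode = rng.random(n_bg) < 0.6
    bg_means = np.where(
        low_mode, rng.beta(2.0, 10.0, size=n_bg), rng.beta(10.0, 2.0, size=n_bg)
    )
    betas[n_age + n_reg :] = bg_means[:, None]

    if config.noise_sd > 0:
        betas += rng.normal(0.0, config.noise_sd, size=(p, n))

    outliers: list[str] = []
    if config.n_outlier_samples > 0:
        idx = rng.choice(n, size=config.n_outlier_samples, replace=False)
        betas[:, idx] += config.outlier_shift
        outliers = [samples[i] for i in sorted(idx)]

    betas = np.clip(betas, 0.0, 1.0)
    matrix = BetaMatrix(pd.DataFrame(betas, index=probes, columns=samples))

    # survival linked to the planted adaptive score (latent biological age):
    # the High group's hazard is HR times the Low group's
    bioage_series = pd.Series(bioage, index=samples, name="bioage")
    adaptive_group = pd.Series(
        np.where(bioage_series > bioage_series.median(), "High", "Low"),
        index=samples,
    )
    os_months, os_event = draw_survival(
        adaptive_group.to_numpy() == "High", config, rng
    )

    clin = pd.DataFrame(
        {
            "age_years": age,
            "sex": rng.choice(["F", "M"], size=n),
            "karyotype_normal": 1,
            "risk_group": rng.choice(["favorable", "intermediate", "poor"], size=n),
            "os_months": os_months,
            "os_event": os_event,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    for label in config.mutation_fractions:
        clin[f"{label}_mut"] = (groups == label).astype(int)
    for j in range(config.n_decoy_genes):
        carriers = rng.random(n) < config.decoy_gene_carrier_fraction
        clin[f"DECOY{j}_mut"] = carriers.astype(int)

    region_probe_ids = config.region_probe_ids()
    membership = {
        probe: i // config.probes_per_region for i, probe in enumerate(region_probe_ids)
    }
    dmc_probes = {
        label: list(region_probe_ids)
        for label, s in config.prc2_mutation_shift.items()
        if s != 0
    }
    tss_regions = list(range(0, config.n_prc2_regions, 2))  # every other region

    truth = SyntheticTruth(
        bioage=bioage_series,
        group_labels=groups,
        outlier_samples=outliers,
        dmc_probes=dmc_probes,
        age_cpgs=config.age_cpg_ids(),
        region_membership=membership,
        region_baselines=region_baselines,
        adaptive_group=adaptive_group,
        tss_regions=tss_regions,
    )
    return matrix, CohortTable(clin), truth


# ---------------------------------------------------------------------------
# Regions, manifest, TSS
# ---------------------------------------------------------------------------

PROBE_SPACING = 1000  # bp between consecutive probes on the synthetic chromosome


def generate_regions(
    config: SyntheticCohortConfig,
) -> tuple[dict[str, RegionSet], ProbeManifest, list[tuple[str, int]]]:
    """Peak sets per TF, probe manifest, and TSS coordinates.

    All probes sit on one synthetic chromosome at 1-based positions
    ``PROBE_SPACING * (i + 1)``. Each planted PRC2 region spans its probes;
    the EZH2-like and SUZ12-like peak sets cover the same regions with
    different flanks, so their intersection recovers exactly the planted
    regions. Decoy TFs get peaks over disjoint background-probe blocks.
    TSS coordinates (0-based) are placed inside every other PRC2 region.
    """
    if config.n_prc2_regions < 1:
        raise ConfigError("need at least one PRC2 region")
    rng = np.random.default_rng(config.seed + 1)
    probes = config.all_probe_ids()
    pos = [(i + 1) * PROBE_SPACING for i in range(config.n_probes)]  # 1-based
    manifest = ProbeManifest(
        pd.DataFrame(
            {"chrom": "chrS", "pos": pos}, index=pd.Index(probes, name="probe_id")
        )
    )

    def probe_block_interval(first: int, count: int, flank: int) -> tuple[str, int, int]:
        # 0-based half-open interval covering probes [first, first+count)
        start0 = (first + 1) * PROBE_SPACING - 1
        end0 = (first + count) * PROBE_SPACING  # position of last probe, exclusive
        return ("chrS", max(0, start0 - flank), end0 + flank)

    n_age = config.n_age_cpgs
    ppr = config.probes_per_region
    ezh2, suz12 = [], []
    for r in range(config.n_prc2_regions):
        first = n_age + r * ppr
        ezh2.append(probe_block_interval(first, ppr, flank=200))
        suz12.append(probe_block_interval(first, ppr, flank=350))
    peaks: dict[str, RegionSet] = {
        "EZH2": RegionSet.from_tuples(ezh2),
        "SUZ12": RegionSet.from_tuples(suz12),
    }

    # decoy TFs: disjoint blocks of background probes, no planted signal
    n_bg_start = n_age + config.n_region_probes
    bg_count = config.n_probes - n_bg_start
    peaks_per_decoy = 10
    block = 3
    for j in range(config.n_decoy_tfs):
        firsts = rng.choice(
            max(bg_count - block, 1), size=min(peaks_per_decoy, bg_count), replace=False
        )
        tuples = [probe_block_interval(n_bg_start + int(f), block, flank=100) for f in sorted(firsts)]
        peaks[f"DECOY_TF{j}"] = RegionSet.from_tuples(tuples)

    tss: list[tuple[str, int]] = []
    for r in range(0, config.n_prc2_regions, 2):
        first = n_age + r * ppr
        tss.append(("chrS", (first + 1) * PROBE_SPACING))  # 0-based, inside region
    return peaks, manifest, tss


# ---------------------------------------------------------------------------
# Clocks
# ---------------------------------------------------------------------------


def generate_clock(
    name: str,
    cpgs: list[str],
    weights: list[float],
    intercept: float,
    calibration: str = "identity",
    adult_age: float = 20.0,
    requires_normalization: bool = False,
) -> ClockDefinition:
    """Build a clock definition from explicit coefficients."""
    if len(cpgs) != len(set(cpgs)):
        raise ConfigError("duplicate CpG IDs in clock definition")
    if len(cpgs) != len(weights):
        raise ConfigError("cpgs and weights must have equal length")
    return ClockDefinition(
        name=name,
        intercept=intercept,
        weights=dict(zip(cpgs, (float(w) for w in weights))),
        calibration=calibration,
        adult_age=adult_age,
        requires_normalization=requires_normalization,
    )


def make_adaptive_clock(config: SyntheticCohortConfig, name: str = "adaptage_like") -> ClockDefinition:
    """An identity-calibration clock that recovers the latent biological age.

    Age CpGs were planted as beta = 0.4 + slope * (bioage - mid_age), so the
    inverse linear map over the k age CpGs — weights 1 / (k * slope) and a
    matching intercept — returns the biological age in years.
    """
    cpgs = config.age_cpg_ids()
    k = len(cpgs)
    mid_age = sum(config.age_range) / 2.0
    w = 1.0 / (k * config.age_slope)
    intercept = mid_age - 0.4 / config.age_slope
    return generate_clock(name, cpgs, [w] * k, intercept, calibration="identity")


def make_pantissue_like_clock(
    config: SyntheticCohortConfig, name: str = "pantissue_like", adult_age: float = 20.0
) -> ClockDefinition:
    """A log-linear-adult calibrated clock over the same planted age CpGs.

    The linear predictor reproduces F(bioage) (the pan-tissue training
    transform), exercising the calibration inversion path and the
    normalization-required pairing.
    """
    cpgs = config.age_cpg_ids()
    k = len(cpgs)
    # predictor = (mean beta - 0.4) / slope / (adult_age + 1) approximates the
    # adult branch of F; exact for bioage >= adult_age
    w = 1.0 / (k * config.age_slope * (adult_age + 1))
    mid_age = sum(config.age_range) / 2.0
    intercept = (mid_age - adult_age) / (adult_age + 1) - 0.4 / (
        config.age_slope * (adult_age + 1)
    )
    return generate_clock(
        name,
        cpgs,
        [w] * k,
        intercept,
        calibration="log_linear_adult",
        adult_age=adult_age,
        requires_normalization=True,
    )


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------


def write_cohort(
    out_dir: str | Path, config: SyntheticCohortConfig
) -> dict[str, Path]:
    """Generate a cohort and emit every file the pipeline consumes.

    Returns the paths written: beta matrix TSV, clinical TSV, manifest TSV,
    one BED per TF, two clock CSVs, TSS TSV and truth JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, cohort, truth = generate_cohort(config)
    peaks, manifest, tss = generate_regions(config)

    paths: dict[str, Path] = {}
    paths["beta"] = out / "beta.tsv"
    write_beta_matrix(matrix, paths["beta"])
    paths["clinical"] = out / "clinical.tsv"
    write_clinical(cohort, paths["clinical"])
    paths["manifest"] = out / "manifest.tsv"
    write_manifest(manifest, paths["manifest"])
    peaks_dir = out / "peaks"
    peaks_dir.mkdir(exist_ok=True)
    for tf, regions in peaks.items():
        paths[f"peaks_{tf}"] = peaks_dir / f"{tf}.bed"
        write_bed(regions, paths[f"peaks_{tf}"])
    paths["clock_adaptive"] = out / "adaptage_like.csv"
    write_clock(make_adaptive_clock(config), paths["clock_adaptive"])
    paths["clock_pantissue"] = out / "pantissue_like.csv"
    write_clock(make_pantissue_like_clock(config), paths["clock_pantissue"])
    paths["tss"] = out / "tss.tsv"
    pd.DataFrame(tss, columns=["chrom", "pos"]).to_csv(
        paths["tss"], sep="\t", index=False
    )
    paths["truth"] = out / "truth.json"
    write_json(truth.to_json_dict(), paths["truth"])
    return paths
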