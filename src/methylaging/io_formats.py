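"""Readers and writers for every file format the pipeline touches.

All tabular formats are plain TSV/CSV handled through pandas; genomic
intervals are BED (0-based, half-open); clock coefficient files are CSV with
a dedicated ``(Intercept)`` row, mirroring how published clock coefficient
tables are distributed. Readers validate aggressively and raise
:class:`FormatError` with messages that name the offending probe, sample or
line; writers emit files their readers accept unchanged.

Probe manifest positions are 1-based (array-manifest convention). For
overlap arithmetic they are converted to 0-based half-open single-base
intervals ``[pos - 1, pos)`` so that all interval algebra lives in one
coordinate system.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .regions import RegionSet


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Beta matrix
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Probes x samples matrix of methylation beta values in [0, 1].

    ``values`` is a float DataFrame indexed by probe ID with sample IDs as
    columns. Missing betas are ``NaN``; each operation states its own
    missing-data policy.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
            raise FormatError(f"duplicate probe IDs: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()[:5]
            raise FormatError(f"duplicate sample IDs: {dupes}")
        arr = df.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise FormatError(
                f"beta value {arr[i, j]!r} outside [0, 1] at probe "
                f"{df.index[i]!r}, sample {df.columns[j]!r}"
            )
        self.values = df.astype(float)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[:, list(sample_ids)].copy())

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probe_ids), :].copy())


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    """Read a probes x samples beta matrix from TSV/CSV (probe ID first column)."""
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric beta value ({exc})") from exc
    try:
        return BetaMatrix(df)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_beta_matrix(matrix: BetaMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="probe_id", na_rep="NA")


# ---------------------------------------------------------------------------
# Probe manifest
# ---------------------------------------------------------------------------


@dataclass
class ProbeManifest:
    """Maps probe ID to a 1-based genomic position (chrom, pos)."""

    table: pd.DataFrame  # index: probe_id; columns: chrom, pos

    def __post_init__(self) -> None:
        df = self.table
        if df.index.has_duplicates:
            raise FormatError("duplicate probe IDs in manifest")
        if (df["pos"] < 1).any():
            bad = df.index[df["pos"] < 1][0]
            raise FormatError(f"manifest position < 1 for probe {bad!r}")
        self.table = df.assign(pos=df["pos"].astype(int))

    def position(self, probe_id: str) -> tuple[str, int]:
        row = self.table.loc[probe_id]
        return str(row["chrom"]), int(row["pos"])

    def as_intervals(self) -> RegionSet:
        """Probes as 0-based half-open single-base intervals [pos-1, pos)."""
        df = self.table
        return RegionSet.from_arrays(
            df["chrom"].to_numpy(),
            df["pos"].to_numpy() - 1,
            df["pos"].to_numpy(),
            names=df.index.to_numpy(),
        )

    def __len__(self) -> int:
        return len(self.table)


def read_manifest(path: str | Path) -> ProbeManifest:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    required = {"probe_id", "chrom", "pos"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: manifest needs columns {sorted(required)}")
    return ProbeManifest(df.set_index("probe_id"))


def write_manifest(manifest: ProbeManifest, path: str | Path) -> None:
    manifest.table.to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# Clock definitions
# ---------------------------------------------------------------------------

INTERCEPT_ROW = "(Intercept)"


@dataclass
class ClockDefinition:
    """A named linear epigenetic clock: intercept + per-CpG weights.

    ``calibration`` is ``"identity"`` (causality-enriched clocks report the
    linear predictor directly, in years) or ``"log_linear_adult"`` (the
    pan-tissue convention: the predictor lives on a transformed age scale and
    is inverted through :func:`methylaging.clocks.calibrate`).
    """

    name: str
    intercept: float
    weights: dict[str, float]
    calibration: str = "identity"
    adult_age: float = 20.0
    requires_normalization: bool = False

    def __post_init__(self) -> None:
        if not self.weights:
            raise FormatError(f"clock {self.name!r} has no CpG weights")
        if self.calibration not in ("identity", "log_linear_adult"):
            raise FormatError(f"unknown calibration mode {self.calibration!r}")
        if self.calibration == "log_linear_adult" and not self.adult_age > 0:
            raise FormatError("adult_age must be > 0 for log_linear_adult")

    @property
    def cpgs(self) -> list[str]:
        return list(self.weights)


def read_clock(path: str | Path, name: str | None = None) -> ClockDefinition:
    """Read a clock CSV: columns ``cpg, weight`` plus one ``(Intercept)`` row.

    Optional metadata columns ``calibration``, ``adult_age`` and
    ``requires_normalization`` are taken from the intercept row.
    """
    df = pd.read_csv(path, dtype={"cpg": str})
    if not {"cpg", "weight"}.issubset(df.columns):
        raise FormatError(f"{path}: clock CSV needs columns 'cpg' and 'weight'")
    is_int = df["cpg"] == INTERCEPT_ROW
    if is_int.sum() == 0:
        raise FormatError(f"{path}: missing {INTERCEPT_ROW!r} row")
    if is_int.sum() > 1:
        raise FormatError(f"{path}: {int(is_int.sum())} intercept rows, expected 1")
    body = df.loc[~is_int]
    if body["cpg"].duplicated().any():
        dupes = body.loc[body["cpg"].duplicated(), "cpg"].tolist()[:5]
        raise FormatError(f"{path}: duplicate CpG IDs: {dupes}")
    meta = df.loc[is_int].iloc[0]
    calibration = str(meta.get("calibration", "identity"))
    if calibration in ("", "nan"):
        calibration = "identity"
    adult_age = float(meta["adult_age"]) if "adult_age" in df.columns and pd.notna(meta.get("adult_age")) else 20.0
    requires_norm = bool(meta.get("requires_normalization", False)) if "requires_normalization" in df.columns else False
    return ClockDefinition(
        name=name or Path(path).stem,
        intercept=float(meta["weight"]),
        weights=dict(zip(body["cpg"], body["weight"].astype(float))),
        calibration=calibration,
        adult_age=adult_age,
        requires_normalization=requires_norm,
    )


def write_clock(clock: ClockDefinition, path: str | Path) -> None:
    rows = [
        {
            "cpg": INTERCEPT_ROW,
            "weight": clock.intercept,
            "calibration": clock.calibration,
            "adult_age": clock.adult_age,
            "requires_normalization": clock.requires_normalization,
        }
    ]
    rows.extend(
        {
            "cpg": cpg,
            "weight": w,
            "calibration": "",
            "adult_age": "",
            "requires_normalization": "",
        }
        for cpg, w in clock.weights.items()
    )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Clinical / cohort table
# ---------------------------------------------------------------------------

CLINICAL_REQUIRED = ("sample_id", "age_years", "os_months", "os_event")


@dataclass
class CohortTable:
    """Per-sample clinical annotation: age, group labels, survival.

    ``table`` is indexed by sample ID. Mutation flags are 0/1 columns named
    ``<gene>_mut``; arbitrary extra label columns (sex, karyotype_normal,
    risk_group ...) pass through untouched.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        if df.index.has_duplicates:
            raise FormatError("duplicate sample IDs in clinical table")
        if "age_years" in df.columns and (df["age_years"] <= 0).any():
            bad = df.index[df["age_years"] <= 0][0]
            raise FormatError(f"non-positive age for sample {bad!r}")
        if "os_months" in df.columns and (df["os_months"] < 0).any():
            bad = df.index[df["os_months"] < 0][0]
            raise FormatError(f"negative survival time for sample {bad!r}")
        if "os_event" in df.columns and not df["os_event"].isin([0, 1]).all():
            raise FormatError("os_event must be 0 or 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def ages(self) -> pd.Series:
        return self.table["age_years"]

    def mutation_genes(self) -> list[str]:
        return [c[: -len("_mut")] for c in self.table.columns if c.endswith("_mut")]

    def carriers(self, gene: str) -> pd.Index:
        col = f"{gene}_mut"
        return self.table.index[self.table[col] == 1]

    def __len__(self) -> int:
        return len(self.table)


def read_clinical(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: clinical table missing columns {missing}")
    return CohortTable(df.set_index("sample_id"))


def write_clinical(cohort: CohortTable, path: str | Path) -> None:
    cohort.table.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------


def read_bed(path: str | Path) -> RegionSet:
    """Read BED3 or BED with a score column (0-based, half-open).

    Output intervals are sorted by (chrom, start); ``start >= end`` or
    non-numeric coordinates are rejected.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    scores: list[float] = []
    have_score = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric coordinates {parts[1]!r}/{parts[2]!r}"
                ) from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            chroms.append(parts[0])
            starts.append(start)
            ends.append(end)
            if len(parts) >= 5:
                # BED5: name, score; BED4 with numeric col 4 treated as score
                try:
                    scores.append(float(parts[4]))
                    have_score = True
                except ValueError:
                    scores.append(np.nan)
            elif len(parts) == 4:
                try:
                    scores.append(float(parts[3]))
                    have_score = True
                except ValueError:
                    scores.append(np.nan)
            else:
                scores.append(np.nan)
    return RegionSet.from_arrays(
        np.asarray(chroms, dtype=object),
        np.asarray(starts, dtype=int),
        np.asarray(ends, dtype=int),
        scores=np.asarray(scores, dtype=float) if have_score else None,
    )


def write_bed(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in regions:
            if regions.scores is None or np.isnan(iv.score):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{iv.score:g}\n")


# ---------------------------------------------------------------------------
# JSON (truth, reports)
# ---------------------------------------------------------------------------


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _sniff_sep(path: str | Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","
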