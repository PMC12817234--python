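"""Linear epigenetic clocks and age-acceleration computation.

An epigenetic clock is a linear predictor over CpG beta values,
``s_i = intercept + sum_g w_g * beta_{g,i}``, optionally followed by a
calibration transform to the year scale. Two calibrations are supported:

* ``identity`` — the predictor already is an age in years (the convention
  of causality-enriched clocks such as AdaptAge/DamAge/CausAge);
* ``log_linear_adult`` — the pan-tissue convention: the model was trained
  on ``F(age) = log(age + 1) - log(adult_age + 1)`` below ``adult_age`` and
  on ``(age - adult_age) / (adult_age + 1)`` above it, so the predictor is
  inverted through :func:`calibrate`.

Epigenetic age acceleration (EAA) is the plain difference EA minus
chronological age. No residual-regression adjustment is applied: in
leukemic cohorts the EA-age relation is not linear, so a residual-based
EAA would be built on a regression that does not fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import BetaMatrix, ClockDefinition


@dataclass
class ClockApplication:
    """Per-sample linear predictor plus bookkeeping about imputed CpGs."""

    linear_predictor: pd.Series
    n_missing_cpgs: int
    missing_cpgs: list[str]


def apply_clock(
    matrix: BetaMatrix,
    clock: ClockDefinition,
    missing_policy: str = "error",
) -> ClockApplication:
    """Evaluate a clock's linear predictor on every sample.

    ``missing_policy`` is ``"error"`` (raise listing absent clock CpGs) or
    ``"mean_impute"`` (an absent CpG contributes the cohort mean of present
    samples at that CpG; a CpG absent from the matrix entirely contributes
    0.5). Per-sample NaNs at present CpGs are mean-imputed across samples
    under ``mean_impute`` and rejected under ``error``.
    """
    if missing_policy not in ("error", "mean_impute"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    cpgs = clock.cpgs
    present = [c for c in cpgs if c in matrix.values.index]
    absent = [c for c in cpgs if c not in matrix.values.index]
    if missing_policy == "error" and absent:
        raise KeyError(
            f"clock {clock.name!r}: {len(absent)} CpGs absent from matrix: "
            f"{absent[:10]}{'...' if len(absent) > 10 else ''}"
        )
    sub = matrix.values.loc[present]
    n_imputed = len(absent)
    if missing_policy == "error":
        if sub.isna().any().any():
            bad = sub.index[sub.isna().any(axis=1)][:10].tolist()
            raise ValueError(f"clock {clock.name!r}: NaN betas at CpGs {bad}")
    else:
        n_imputed += int(sub.isna().to_numpy().sum())
        row_means = sub.mean(axis=1, skipna=True).fillna(0.5)
        sub = sub.apply(lambda row: row.fillna(row_means[row.name]), axis=1)
    w = np.array([clock.weights[c] for c in present])
    s = clock.intercept + w @ sub.to_numpy(dtype=float)
    # absent CpGs under mean_impute: no cohort information, contribute 0.5
    if missing_policy == "mean_impute" and absent:
        s = s + sum(clock.weights[c] * 0.5 for c in absent)
    return ClockApplication(
        linear_predictor=pd.Series(s, index=matrix.sample_ids, name=clock.name),
        n_missing_cpgs=n_imputed,
        missing_cpgs=absent,
    )


def forward_calibration(age, adult_age: float = 20.0):
    """The pan-tissue training transform F(age); inverse of :func:`calibrate`."""
    age = np.asarray(age, dtype=float)
    low = np.log(age + 1) - np.log(adult_age + 1)
    high = (age - adult_age) / (adult_age + 1)
    out = np.where(age <= adult_age, low, high)
    return out if out.ndim else float(out)


def calibrate(linear_predictor, clock: ClockDefinition):
    """Map a clock's linear predictor to years.

    Identity calibration returns the predictor unchanged. Log-linear-adult
    inverts the training transform: a negative predictor maps to
    ``exp(s) * (adult_age + 1) - 1`` (childhood branch), a non-negative one
    to ``s * (adult_age + 1) + adult_age`` (adult branch). The inverse is
    continuous and strictly increasing.
    """
    s = np.asarray(linear_predictor, dtype=float)
    if clock.calibration == "identity":
        out = s
    else:
        aa = clock.adult_age
        out = np.where(s < 0, np.exp(s) * (aa + 1) - 1, s * (aa + 1) + aa)
    if isinstance(linear_predictor, pd.Series):
        return pd.Series(out, index=linear_predictor.index, name=linear_predictor.name)
    return out if out.ndim else float(out)


def compute_epigenetic_age(
    matrix: BetaMatrix,
    clock: ClockDefinition,
    missing_policy: str = "error",
) -> pd.Series:
    """Epigenetic age per sample: calibrated linear predictor in years."""
    app = apply_clock(matrix, clock, missing_policy=missing_policy)
    return calibrate(app.linear_predictor, clock)


def compute_eaa(
    epigenetic_age: pd.Series, chronological_age: pd.Series
) -> pd.DataFrame:
    """Epigenetic age acceleration: EAA = EA - chronological age.

    Samples missing a chronological age are dropped (their count appears in
    the result's ``attrs['n_skipped']``).
    """
    age = chronological_age.reindex(epigenetic_age.index)
    keep = age.notna()
    out = pd.DataFrame(
        {
            "epigenetic_age": epigenetic_age[keep],
            "chronological_age": age[keep],
            "eaa": epigenetic_age[keep] - age[keep],
        }
    )
    out.attrs["n_skipped"] = int((~keep).sum())
    return out


def run_clock(
    matrix: BetaMatrix,
    clock: ClockDefinition,
    chronological_age: pd.Series,
    missing_policy: str = "error",
) -> pd.DataFrame:
    """Full clock pipeline: predictor -> calibration -> EAA table."""
    ea = compute_epigenetic_age(matrix, clock, missing_policy=missing_policy)
    result = compute_eaa(ea, chronological_age)
    result.insert(0, "clock", clock.name)
    return result
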