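"""Plate-count (CFU) assay analytics.

Survival on a nanostructured surface is quantified against a separately
incubated no-surface control: the viable fraction is the ratio of
dilution-corrected mean CFU counts, the killing rate converts a surviving
fraction into cells killed per hour per cm^2 of surface, and two surfaces
are compared by an unpaired two-tailed t-test on per-replicate viable
fractions (Student's pooled-variance test by default, Welch optional).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ASSAY_COLUMNS",
    "TTestResult",
    "read_assay_table",
    "validate_assay_table",
    "viable_fraction",
    "replicate_fractions",
    "killing_rate",
    "compare_killing",
]

ASSAY_COLUMNS = [
    "surface_id",
    "timepoint_h",
    "replicate",
    "cfu_count",
    "dilution_factor",
    "well_type",
]


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    pvalue: float


def validate_assay_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ASSAY_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"assay table missing columns {missing}")
    if (table["cfu_count"] < 0).any():
        raise ValueError("cfu_count must be non-negative")
    if (table["dilution_factor"] < 1).any():
        raise ValueError("dilution_factor must be >= 1")
    bad = set(table["well_type"]) - {"surface", "control"}
    if bad:
        raise ValueError(f"unknown well_type values {sorted(bad)}")
    surface_tp = set(
        map(tuple, table.loc[table.well_type == "surface", ["timepoint_h"]].values)
    )
    control_tp = set(
        map(tuple, table.loc[table.well_type == "control", ["timepoint_h"]].values)
    )
    if not surface_tp <= control_tp:
        raise ValueError(
            "every surface timepoint needs a matching control timepoint; "
            f"missing controls for {sorted(surface_tp - control_tp)}"
        )
    return table


def read_assay_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a CFU table (CSV with the ASSAY_COLUMNS header)."""
    return validate_assay_table(pd.read_csv(path))


def _corrected_counts(
    table: pd.DataFrame, well_type: str, timepoint: float, surface_id: str | None = None
) -> np.ndarray:
    mask = (table.well_type == well_type) & np.isclose(
        table.timepoint_h.astype(float), timepoint
    )
    if surface_id is not None:
        mask &= table.surface_id == surface_id
    sub = table.loc[mask]
    return (sub.cfu_count * sub.dilution_factor).to_numpy(dtype=float)


def replicate_fractions(
    table: pd.DataFrame, surface_id: str, timepoint: float
) -> np.ndarray:
    """Per-replicate viable fractions: surface counts over the control mean."""
    surface = _corrected_counts(table, "surface", timepoint, surface_id)
    control = _corrected_counts(table, "control", timepoint)
    if surface.size == 0:
        raise ValueError(
            f"no surface wells for {surface_id!r} at t={timepoint} h"
        )
    if control.size == 0 or control.mean() == 0:
        raise ValueError(
            f"control mean count is zero or absent at t={timepoint} h: "
            "viable fraction undefined"
        )
    return surface / control.mean()


def viable_fraction(
    table: pd.DataFrame,
    surface_id: str,
    timepoint: float,
    with_se: bool = False,
) -> float | tuple[float, float]:
    """Mean viable fraction of a surface relative to the no-surface control.

    Ratio of dilution-corrected mean CFU counts; can exceed 1 (net growth)
    although the assay design precludes it.  With ``with_se=True`` also
    returns a delta-method standard error combining surface-replicate and
    control-replicate variability.
    """
    fractions = replicate_fractions(table, surface_id, timepoint)
    frac = float(fractions.mean())
    if not with_se:
        return frac
    control = _corrected_counts(table, "control", timepoint)
    var_s = fractions.var(ddof=1) / fractions.size if fractions.size > 1 else 0.0
    rel_var_c = (
        control.var(ddof=1) / control.size / control.mean() ** 2
        if control.size > 1
        else 0.0
    )
    se = math.sqrt(var_s + frac**2 * rel_var_c)
    return frac, se


def killing_rate(
    initial_count: float,
    fraction_surviving: float,
    duration_h: float,
    area_cm2: float,
) -> float:
    """Cells killed per hour per cm^2: ``N0*(1 - f)/(t*A)``.

    A surviving fraction above 1 (net growth) yields a negative rate and a
    warning rather than an error.
    """
    if duration_h <= 0 or area_cm2 <= 0:
        raise ValueError("duration and area must be positive")
    if fraction_surviving > 1:
        import warnings

        warnings.warn(
            f"surviving fraction {fraction_surviving} > 1: net growth, "
            "killing rate is negative",
            stacklevel=2,
        )
    return initial_count * (1.0 - fraction_surviving) / (duration_h * area_cm2)


def compare_killing(
    table: pd.DataFrame,
    surface_a: str,
    surface_b: str,
    timepoint: float,
    test: str = "student",
) -> TTestResult:
    """Unpaired two-tailed t-test on per-replicate viable fractions.

    ``test="student"`` uses the pooled-variance Student test,
    ``test="welch"`` the unequal-variance variant.  Two groups with zero
    variance and equal means return p = 1 by convention.
    """
    if test not in ("student", "welch"):
        raise ValueError(f"test must be 'student' or 'welch', got {test!r}")
    a = replicate_fractions(table, surface_a, timepoint)
    b = replicate_fractions(table, surface_b, timepoint)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicates per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(statistic=0.0, df=a.size + b.size - 2, pvalue=1.0)
        return TTestResult(statistic=math.inf, df=a.size + b.size - 2, pvalue=0.0)
    res = stats.ttest_ind(a, b, equal_var=(test == "student"))
    return TTestResult(
        statistic=float(res.statistic), df=float(res.df), pvalue=float(res.pvalue)
    )
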