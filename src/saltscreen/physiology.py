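"""Physiological indicator formulas and time-course summaries.

Covers relative electrolyte leakage from conductivity pairs, chlorophyll
content from 95 % ethanol-extract absorbances, Na+/K+ ratios, signed percent
change between condition means, and mean/SD summaries of replicated
indicator time courses. Assay chemistry (Pro, MDA, ROS, enzyme activities)
is out of scope: those indicators enter as externally measured values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Closed indicator vocabulary for time-course tables.
INDICATORS: tuple[str, ...] = ("Pro", "MDA", "O2-", "H2O2", "POD", "CAT", "SOD", "REL")

#: Sampling days used in the stress time course.
DAYS: tuple[int, ...] = (0, 1, 3, 6)

__all__ = [
    "INDICATORS",
    "DAYS",
    "PigmentResult",
    "relative_electrolyte_leakage",
    "chlorophyll_content",
    "percent_change",
    "na_k_ratio",
    "summarize_timecourse",
]


def relative_electrolyte_leakage(s1: float, s2: float) -> float:
    """Relative electrolyte leakage (S1 / S2) x 100 %.

    S1 is the initial conductivity of the leaf soak, S2 the conductivity
    after boiling (total electrolytes). S1 > S2 is physically impossible but
    occurs in noisy instrument exports; it is tolerated with a warning and a
    value above 100 is returned.
    """
    if s2 <= 0:
        raise ValueError(f"post-boil conductivity S2 must be > 0, got {s2!r}")
    if s1 < 0:
        raise ValueError(f"initial conductivity S1 must be >= 0, got {s1!r}")
    if s1 > s2:
        warnings.warn(
            f"S1 ({s1}) exceeds S2 ({s2}); leakage > 100 % returned", stacklevel=2
        )
    return 100.0 * s1 / s2


@dataclass(frozen=True)
class PigmentResult:
    """Chlorophyll concentrations (mg/L extract) and per-g-FW contents (mg/g)."""

    chl_a: float
    chl_b: float
    chl_total: float
    chl_a_fw: float
    chl_b_fw: float
    chl_total_fw: float


def chlorophyll_content(
    a665: float,
    a649: float,
    a470: float | None = None,
    *,
    extract_volume_l: float = 0.025,
    tissue_mass_g: float = 0.2,
) -> PigmentResult:
    """Chlorophyll a/b from ethanol-extract absorbances.

    Chl a = 13.95*A665 - 6.88*A649 and Chl b = 24.96*A649 - 7.32*A665
    (mg/L in the extract); total is their sum. Per-gram-fresh-weight content
    scales by extract volume over tissue mass. Negative concentrations
    (possible on noisy absorbances) are clipped to 0 with a warning.

    A470 is accepted and ignored: it is recorded by the assay but no
    published equation consumes it here, and no carotenoid formula is
    guessed.
    """
    del a470  # measured but unused; no equation provided for it
    if a665 < 0 or a649 < 0:
        raise ValueError("absorbances must be non-negative")
    if extract_volume_l <= 0:
        raise ValueError(f"extract volume must be > 0 L, got {extract_volume_l!r}")
    if tissue_mass_g <= 0:
        raise ValueError(f"tissue mass must be > 0 g, got {tissue_mass_g!r}")

    chl_a = 13.95 * a665 - 6.88 * a649
    chl_b = 24.96 * a649 - 7.32 * a665
    if chl_a < 0 or chl_b < 0:
        warnings.warn(
            "negative pigment concentration computed; clipped to 0", stacklevel=2
        )
        chl_a = max(chl_a, 0.0)
        chl_b = max(chl_b, 0.0)
    chl_total = chl_a + chl_b
    scale = extract_volume_l / tissue_mass_g
    return PigmentResult(
        chl_a=chl_a,
        chl_b=chl_b,
        chl_total=chl_total,
        chl_a_fw=chl_a * scale,
        chl_b_fw=chl_b * scale,
        chl_total_fw=chl_total * scale,
    )


def percent_change(control_mean: float, treated_mean: float) -> float:
    """Signed percent change of the treated mean relative to control:
    100 * (treated - control) / control."""
    if control_mean == 0:
        raise ValueError("control mean is zero; percent change undefined")
    return 100.0 * (treated_mean - control_mean) / control_mean


def na_k_ratio(na: float, k: float) -> float:
    """Na+/K+ concentration ratio for one tissue (same units for both ions)."""
    if k <= 0:
        raise ValueError(f"K+ concentration must be > 0, got {k!r}")
    if na < 0:
        raise ValueError(f"Na+ concentration must be >= 0, got {na!r}")
    return na / k


def summarize_timecourse(series: pd.DataFrame) -> pd.DataFrame:
    """Mean, sample SD (n-1 denominator) and n per (variety, indicator, day).

    Input is a tidy table with columns ``variety, indicator, day, replicate,
    value``. Cells with a single replicate report SD as missing (NaN);
    absent cells are simply absent from the output.
    """
    required = {"variety", "indicator", "day", "replicate", "value"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"time-course table missing columns: {sorted(missing)}")
    if series.empty:
        raise ValueError("empty time-course table")
    bad = set(series["indicator"]) - set(INDICATORS)
    if bad:
        raise ValueError(f"unknown indicator labels {sorted(bad)}")
    bad_days = set(series["day"]) - set(DAYS)
    if bad_days:
        raise ValueError(f"unknown days {sorted(bad_days)}; expected {DAYS}")
    out = (
        series.groupby(["variety", "indicator", "day"], sort=True)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    out.loc[out["n"] < 2, "sd"] = np.nan
    return out
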