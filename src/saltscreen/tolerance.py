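"""Germplasm salt-tolerance evaluation.

Implements the screening chain used to rank accessions under salt stress:
per-trait salt-tolerance coefficients (relative traits), min-max membership
scores, the equal-weight composite evaluation value D, the per-trait salt
tolerance index, and a weighted-grade salt injury index.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

#: Closed trait vocabulary: plant height (cm), fresh weight (g), dry weight (g).
TRAITS: tuple[str, ...] = ("PHt", "FW", "DW")

#: Closed condition vocabulary.
CONDITIONS: tuple[str, ...] = ("control", "salt")

__all__ = [
    "TRAITS",
    "CONDITIONS",
    "relative_trait",
    "salt_tolerance_index",
    "membership_scores",
    "composite_d",
    "salt_injury_index",
    "evaluate_accessions",
    "format_scores",
]


def relative_trait(salt_mean: float, control_mean: float) -> float:
    """Salt-tolerance coefficient: salt-condition mean over control mean.

    Parameters
    ----------
    salt_mean : float
        Trait mean under salt treatment (>= 0).
    control_mean : float
        Trait mean under control conditions (> 0).

    Returns
    -------
    float
        The dimensionless relative trait value (RPHt, RFW or RDW).
    """
    if control_mean <= 0:
        raise ValueError(
            f"degenerate control mean {control_mean!r}: must be strictly positive"
        )
    if salt_mean < 0:
        raise ValueError(f"salt-condition mean must be >= 0, got {salt_mean!r}")
    return salt_mean / control_mean


def salt_tolerance_index(salt_value: float, control_value: float) -> float:
    """Salt tolerance index (STI): salt-treated value / control value.

    Identical contract to :func:`relative_trait`; kept as a separately named
    operation because it is reported per trait as its own summary statistic.
    """
    return relative_trait(salt_value, control_value)


def membership_scores(
    values: Sequence[float] | np.ndarray,
    *,
    inverse: bool = False,
    degenerate_value: float = 0.5,
) -> np.ndarray:
    """Min-max membership values for one trait across accessions.

    mu_i = (x_i - min x) / (max x - min x), so the panel minimum maps to 0
    and the maximum to 1. With ``inverse=True`` the complement ``1 - mu`` is
    returned (for cost-type traits where smaller is better).

    If the trait does not vary across accessions (max == min) every
    membership is set to ``degenerate_value`` and a warning is emitted: a
    constant trait carries no ranking information and should not force ties
    at the extremes.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be one-dimensional (one trait across accessions)")
    if x.size < 2:
        raise ValueError(f"need at least 2 accessions, got {x.size}")
    if np.isnan(x).any():
        raise ValueError("values contain NaN")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        warnings.warn(
            "trait is constant across accessions; membership set to "
            f"{degenerate_value} for all",
            stacklevel=2,
        )
        mu = np.full(x.shape, float(degenerate_value))
    else:
        mu = (x - lo) / (hi - lo)
    return 1.0 - mu if inverse else mu


def _normalize_weights(weights: Sequence[float] | None, n_traits: int) -> np.ndarray:
    if weights is None:
        return np.full(n_traits, 1.0 / n_traits)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n_traits,):
        raise ValueError(
            f"weights length {w.size} does not match number of traits {n_traits}"
        )
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must sum to a positive value")
    return w / total


def composite_d(
    mu: Sequence[float] | np.ndarray,
    weights: Sequence[float] | None = None,
) -> np.ndarray | float:
    """Composite evaluation value D = sum_j w_j * mu_j.

    Parameters
    ----------
    mu : array-like
        Membership values, shape ``(n_accessions, n_traits)`` or
        ``(n_traits,)`` for a single accession. All values must lie in
        [0, 1].
    weights : sequence of float, optional
        Per-trait weights (non-negative, normalized to sum to 1). Defaults
        to equal weights, which reproduces the published worked example.

    Returns
    -------
    numpy.ndarray or float
        D per accession (scalar when a single accession was passed).
        Full precision; round to 4 decimals for reporting.
    """
    m = np.asarray(mu, dtype=float)
    single = m.ndim == 1
    if single:
        m = m[None, :]
    if m.ndim != 2:
        raise ValueError("mu must be 1-D or 2-D")
    if np.isnan(m).any():
        raise ValueError("membership values contain NaN")
    if (m < -1e-12).any() or (m > 1 + 1e-12).any():
        raise ValueError("membership values must lie in [0, 1]")
    w = _normalize_weights(weights, m.shape[1])
    d = m @ w
    return float(d[0]) if single else d


def salt_injury_index(
    grade_counts: Mapping[int, int],
    max_grade: int | None = None,
) -> float:
    """Weighted-grade injury percentage for a cohort of scored plants.

    ``100 * sum(grade * count) / (G * total)`` where G is the top grade of
    the scale (by default the largest grade observed). All plants at grade 0
    give 0 %, all at grade G give 100 %. The grading scale is configurable
    because published scales vary.
    """
    if not grade_counts:
        raise ValueError("empty grade counts")
    for g, c in grade_counts.items():
        if g < 0 or int(g) != g:
            raise ValueError(f"grades must be non-negative integers, got {g!r}")
        if c < 0:
            raise ValueError(f"counts must be non-negative, got {c!r} for grade {g}")
    total = sum(grade_counts.values())
    if total < 1:
        raise ValueError("at least one plant required")
    top = max(grade_counts) if max_grade is None else int(max_grade)
    if max_grade is not None and max(grade_counts) > top:
        raise ValueError(f"observed grade {max(grade_counts)} exceeds max_grade {top}")
    if top == 0:
        return 0.0
    weighted = sum(g * c for g, c in grade_counts.items())
    return 100.0 * weighted / (top * total)


_TRAIT_COLUMNS = {"accession", "trait", "condition", "replicate", "value"}


def _validate_trait_table(traits: pd.DataFrame) -> pd.DataFrame:
    missing = _TRAIT_COLUMNS - set(traits.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    bad_trait = set(traits["trait"]) - set(TRAITS)
    if bad_trait:
        raise ValueError(f"unknown trait labels {sorted(bad_trait)}; expected {TRAITS}")
    bad_cond = set(traits["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(
            f"unknown condition labels {sorted(bad_cond)}; expected {CONDITIONS}"
        )
    values = pd.to_numeric(traits["value"], errors="coerce")
    if values.isna().any():
        raise ValueError("non-numeric trait values present")
    if (values < 0).any():
        raise ValueError("trait values must be non-negative")
    return traits.assign(value=values)


def evaluate_accessions(
    traits: pd.DataFrame,
    weights: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Full screening chain from a tidy trait table to ranked D values.

    Replicate values are averaged per (accession, trait, condition); the
    relative trait is the ratio of those means; membership scores are taken
    per trait across accessions and combined into D. Output rows are sorted
    by rank (1 = most tolerant); ties in D are broken by accession id and
    flagged in the ``tied`` column.

    Parameters
    ----------
    traits : pandas.DataFrame
        Tidy table with columns ``accession, trait, condition, replicate,
        value``.
    weights : sequence of float, optional
        Per-trait weights in the order PHt, FW, DW; equal by default.
    """
    traits = _validate_trait_table(traits)
    means = (
        traits.groupby(["accession", "trait", "condition"], sort=True)["value"]
        .mean()
        .unstack(["trait", "condition"])
    )
    for trait in TRAITS:
        for cond in CONDITIONS:
            if (trait, cond) not in means.columns or means[(trait, cond)].isna().any():
                if (trait, cond) in means.columns:
                    bad = means.index[means[(trait, cond)].isna()].tolist()
                else:
                    bad = means.index.tolist()
                raise ValueError(
                    f"accession(s) {bad} missing {cond!r} measurements for trait "
                    f"{trait!r}"
                )

    rel = pd.DataFrame(index=means.index)
    for trait in TRAITS:
        rel[trait] = [
            relative_trait(s, c)
            for s, c in zip(means[(trait, "salt")], means[(trait, "control")])
        ]

    mu = np.column_stack([membership_scores(rel[trait].to_numpy()) for trait in TRAITS])
    d = composite_d(mu, weights)

    out = pd.DataFrame(
        {
            "accession": rel.index,
            "RPHt": rel["PHt"].to_numpy(),
            "RFW": rel["FW"].to_numpy(),
            "RDW": rel["DW"].to_numpy(),
            "mu_RPHt": mu[:, 0],
            "mu_RFW": mu[:, 1],
            "mu_RDW": mu[:, 2],
            "D": d,
        }
    )
    out = out.sort_values(["D", "accession"], ascending=[False, True], kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    out["tied"] = out["D"].duplicated(keep=False)
    return out.reset_index(drop=True)


def format_scores(scores: pd.DataFrame, digits: int = 4) -> pd.DataFrame:
    """Reporting view of :func:`evaluate_accessions` output, rounded to
    ``digits`` decimals (ranks stay integer)."""
    out = scores.copy()
    float_cols = [c for c in out.columns if out[c].dtype.kind == "f"]
    out[float_cols] = out[float_cols].round(digits)
    return out
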