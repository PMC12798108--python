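"""Threshold screening of differential-feature tables, multi-set overlap,
and hypergeometric enrichment with Benjamini-Hochberg FDR control.

Boundary semantics follow the published thresholds literally: |log2FC| >= 1
and VIP >= 1 are inclusive, adjusted p < 0.05 is strict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnnotationSets",
    "screen_degs",
    "screen_dams",
    "multiway_overlap",
    "hypergeometric_enrichment",
    "bh_adjust",
]

_STAT_COLUMNS = {"feature", "log2fc", "adj_p"}


def _validate_stats(stats_df: pd.DataFrame, kind: str, need_vip: bool) -> pd.DataFrame:
    missing = _STAT_COLUMNS - set(stats_df.columns)
    if missing:
        raise ValueError(f"stats table missing columns: {sorted(missing)}")
    if "kind" in stats_df.columns:
        wrong = stats_df.loc[stats_df["kind"] != kind, "feature"]
        if len(wrong):
            raise ValueError(
                f"expected {kind} rows only; offending features: "
                f"{sorted(set(wrong))}"
            )
    if stats_df["feature"].duplicated().any():
        dup = stats_df.loc[stats_df["feature"].duplicated(), "feature"]
        raise ValueError(f"duplicate feature rows: {sorted(set(dup))}")
    lfc = pd.to_numeric(stats_df["log2fc"], errors="coerce")
    p = pd.to_numeric(stats_df["adj_p"], errors="coerce")
    bad = stats_df.loc[lfc.isna() | p.isna() | (p < 0) | (p > 1), "feature"]
    if len(bad):
        raise ValueError(f"malformed statistic rows for features: {sorted(set(bad))}")
    out = stats_df.assign(log2fc=lfc, adj_p=p)
    if need_vip:
        if "vip" not in stats_df.columns:
            raise ValueError("VIP column required for metabolite screening")
        vip = pd.to_numeric(stats_df["vip"], errors="coerce")
        bad = stats_df.loc[vip.isna() | (vip < 0), "feature"]
        if len(bad):
            raise ValueError(f"missing/invalid VIP for features: {sorted(set(bad))}")
        out = out.assign(vip=vip)
    return out


def screen_degs(
    stats_df: pd.DataFrame,
    fc_min: float = 1.0,
    p_max: float = 0.05,
) -> tuple[set, set]:
    """Differentially expressed genes by |log2FC| >= fc_min and adj_p < p_max.

    Returns the (up-regulated, down-regulated) feature-id sets; they are
    disjoint by construction.
    """
    if stats_df.empty:
        return set(), set()
    df = _validate_stats(stats_df, kind="gene", need_vip=False)
    sig = df["adj_p"] < p_max
    up = set(df.loc[sig & (df["log2fc"] >= fc_min), "feature"])
    down = set(df.loc[sig & (df["log2fc"] <= -fc_min), "feature"])
    return up, down


def screen_dams(
    stats_df: pd.DataFrame,
    vip_min: float = 1.0,
    fc_min: float = 1.0,
    p_max: float = 0.05,
) -> tuple[set, set]:
    """Differentially accumulated metabolites: VIP >= vip_min on top of the
    |log2FC| >= fc_min and adj_p < p_max screen. Returns (up, down) sets."""
    if stats_df.empty:
        return set(), set()
    df = _validate_stats(stats_df, kind="metabolite", need_vip=True)
    sig = (df["adj_p"] < p_max) & (df["vip"] >= vip_min)
    up = set(df.loc[sig & (df["log2fc"] >= fc_min), "feature"])
    down = set(df.loc[sig & (df["log2fc"] <= -fc_min), "feature"])
    return up, down


def multiway_overlap(sets: Mapping[str, Iterable]) -> dict[frozenset, int]:
    """Exact exclusive-region counts for k >= 2 labelled sets (Venn regions).

    Returns a mapping from each non-empty label subset (frozenset) to the
    number of features belonging to exactly those sets; all 2**k - 1 regions
    are present (zero counts included), and the counts sum to the size of
    the union.
    """
    labels = list(sets)
    if len(labels) < 2:
        raise ValueError(f"need at least 2 sets, got {len(labels)}")
    as_sets = {lab: set(sets[lab]) for lab in labels}
    membership: dict = {}
    for lab, s in as_sets.items():
        for item in s:
            membership.setdefault(item, set()).add(lab)
    regions = {
        frozenset(combo): 0
        for r in range(1, len(labels) + 1)
        for combo in combinations(labels, r)
    }
    for member_of in membership.values():
        regions[frozenset(member_of)] += 1
    return regions


@dataclass(frozen=True)
class AnnotationSets:
    """Feature annotation sets (e.g. pathways) over a fixed background."""

    sets: Mapping[str, frozenset] = field(default_factory=dict)
    background: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        sets = {k: frozenset(v) for k, v in self.sets.items()}
        background = frozenset(self.background)
        for set_id, members in sets.items():
            if not members:
                raise ValueError(f"annotation set {set_id!r} is empty")
            stray = members - background
            if stray:
                raise ValueError(
                    f"annotation set {set_id!r} has features outside background: "
                    f"{sorted(stray)}"
                )
        object.__setattr__(self, "sets", sets)
        object.__setattr__(self, "background", background)


def hypergeometric_enrichment(
    selected: Iterable,
    annotation: AnnotationSets,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a selection in each set.

    For a set of size K in a background of size N with a selection of size n
    overlapping it in k features, p = P(X >= k) with X ~
    Hypergeometric(N, K, n). BH adjustment is applied across the sets of
    this run.

    Returns a DataFrame with columns ``set_id, set_size, overlap, p, fdr``
    sorted by set id.
    """
    selected = set(selected)
    stray = selected - annotation.background
    if stray:
        raise ValueError(f"selected features outside background: {sorted(stray)}")
    n_bg = len(annotation.background)
    n_sel = len(selected)
    rows = []
    for set_id in sorted(annotation.sets):
        members = annotation.sets[set_id]
        k = len(selected & members)
        # P(X >= k) == sf(k - 1)
        p = float(stats.hypergeom.sf(k - 1, n_bg, len(members), n_sel))
        rows.append((set_id, len(members), k, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["set_id", "set_size", "overlap", "p"])
    out["fdr"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sorted p-values are scaled by m/rank and a running minimum from the
    largest rank down enforces monotonicity; results are capped at 1 and
    order-preserving.
    """
    p = np.asarray(list(p_values) if not isinstance(p_values, np.ndarray) else p_values,
                   dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out
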