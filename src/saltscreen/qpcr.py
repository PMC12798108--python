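"""Relative expression from qPCR Ct values and concordance with RNA-seq.

Relative expression follows the standard delta-delta-Ct procedure:
dCt = Ct(target) - Ct(reference) per well, replicate dCt values are averaged
per group, ddCt = mean dCt(experimental) - mean dCt(control), and
fold = 2**(-ddCt). The negative exponent is the conventional form (higher
expression -> lower Ct -> fold > 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("experimental", "control")

__all__ = ["GROUPS", "relative_expression", "concordance"]

_CT_COLUMNS = {"sample", "group", "gene", "ct_target", "ct_reference"}


def _validate_ct(records: pd.DataFrame) -> pd.DataFrame:
    missing = _CT_COLUMNS - set(records.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    bad_group = set(records["group"]) - set(GROUPS)
    if bad_group:
        raise ValueError(f"unknown group labels {sorted(bad_group)}; expected {GROUPS}")
    for col in ("ct_target", "ct_reference"):
        ct = pd.to_numeric(records[col], errors="coerce")
        if ct.isna().any():
            raise ValueError(f"non-numeric {col} values present")
        out_of_range = records.loc[(ct <= 0) | (ct >= 50), "gene"]
        if len(out_of_range):
            raise ValueError(
                f"{col} outside (0, 50) for gene(s) {sorted(set(out_of_range))}"
            )
    return records


def relative_expression(records: pd.DataFrame) -> pd.DataFrame:
    """Per-gene ddCt and fold change from experimental vs control Ct records.

    Parameters
    ----------
    records : pandas.DataFrame
        Columns ``sample, group, gene, ct_target, ct_reference`` with group
        in {"experimental", "control"}; every gene needs at least one record
        in each group.

    Returns
    -------
    pandas.DataFrame
        Columns ``gene, ddct, fold, log2_fold`` sorted by gene;
        log2_fold == -ddct exactly.
    """
    records = _validate_ct(records)
    dct = records.assign(dct=records["ct_target"] - records["ct_reference"])
    group_means = dct.groupby(["gene", "group"], sort=True)["dct"].mean().unstack()
    for group in GROUPS:
        if group not in group_means.columns or group_means[group].isna().any():
            if group in group_means.columns:
                bad = group_means.index[group_means[group].isna()].tolist()
            else:
                bad = group_means.index.tolist()
            raise ValueError(f"gene(s) {bad} missing {group!r} records")
    ddct = group_means["experimental"] - group_means["control"]
    return pd.DataFrame(
        {
            "gene": ddct.index,
            "ddct": ddct.to_numpy(),
            "fold": np.exp2(-ddct.to_numpy()),
            "log2_fold": -ddct.to_numpy(),
        }
    ).reset_index(drop=True)


def concordance(
    qpcr_log2fc: pd.Series | dict,
    rnaseq_log2fc: pd.Series | dict,
) -> tuple[float, int]:
    """Squared Pearson correlation between qPCR and RNA-seq log2 fold changes.

    Computed over the genes shared by both inputs (keyed by gene id).

    Returns
    -------
    (r_squared, n_shared) : tuple of float and int
    """
    q = pd.Series(qpcr_log2fc, dtype=float)
    r = pd.Series(rnaseq_log2fc, dtype=float)
    shared = q.index.intersection(r.index)
    if len(shared) < 3:
        raise ValueError(
            f"need at least 3 shared genes for concordance, got {len(shared)}"
        )
    rho = stats.pearsonr(q.loc[shared], r.loc[shared]).statistic
    return float(rho**2), int(len(shared))
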