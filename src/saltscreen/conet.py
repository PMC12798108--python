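"""Metabolite-gene co-regulation network.

Pairwise Pearson correlation between metabolite and gene abundance
profiles, BH-FDR control across all tested pairs, |R|/FDR edge thresholds,
degree ranking, and Gephi-ingestible export (edge-list CSV and GEXF).
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CoregNetwork",
    "pairwise_correlation",
    "build_network",
    "degree_ranking",
    "export_network",
    "read_network",
]

EDGE_COLUMNS = ["metabolite", "gene", "r", "p", "fdr", "sign", "weight"]


@dataclass(frozen=True)
class CoregNetwork:
    """Bipartite metabolite-gene network; one row per kept edge."""

    edges: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=EDGE_COLUMNS)
    )

    def __post_init__(self):
        missing = set(EDGE_COLUMNS) - set(self.edges.columns)
        if missing:
            raise ValueError(f"edge table missing columns: {sorted(missing)}")
        edges = self.edges.loc[:, EDGE_COLUMNS].reset_index(drop=True)
        if edges.duplicated(["metabolite", "gene"]).any():
            raise ValueError("duplicate metabolite-gene edges")
        overlap = set(edges["metabolite"]) & set(edges["gene"])
        if overlap:
            raise ValueError(f"ids appear as both metabolite and gene: {sorted(overlap)}")
        object.__setattr__(self, "edges", edges)

    @property
    def metabolites(self) -> list:
        return sorted(set(self.edges["metabolite"]))

    @property
    def genes(self) -> list:
        return sorted(set(self.edges["gene"]))

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        """Undirected bipartite graph with node ``kind`` and edge
        ``sign``/``weight``/``r``/``p``/``fdr`` attributes."""
        g = nx.Graph()
        g.add_nodes_from(self.metabolites, kind="metabolite", bipartite=0)
        g.add_nodes_from(self.genes, kind="gene", bipartite=1)
        for row in self.edges.itertuples(index=False):
            g.add_edge(
                row.metabolite,
                row.gene,
                weight=row.weight,
                sign=row.sign,
                r=row.r,
                p=row.p,
                fdr=row.fdr,
            )
        return g


def _clean_matrix(matrix: pd.DataFrame, label: str) -> pd.DataFrame:
    if matrix.shape[1] < 4:
        raise ValueError(
            f"{label} matrix has {matrix.shape[1]} samples; need at least 4"
        )
    values = matrix.apply(pd.to_numeric, errors="coerce")
    has_missing = values.isna().any(axis=1)
    if has_missing.any():
        warnings.warn(
            f"dropping {label} feature(s) with missing values: "
            f"{sorted(values.index[has_missing])}",
            stacklevel=3,
        )
        values = values.loc[~has_missing]
    zero_var = values.std(axis=1, ddof=1) == 0
    if zero_var.any():
        warnings.warn(
            f"skipping zero-variance {label} feature(s): "
            f"{sorted(values.index[zero_var])}",
            stacklevel=3,
        )
        values = values.loc[~zero_var]
    return values


def pairwise_correlation(
    metabolites: pd.DataFrame,
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson R and two-sided p for every metabolite x gene pair.

    Both matrices are features x samples with identical sample columns in
    identical order. Features with missing values or zero variance are
    dropped with a warning. The p-value uses the exact t reference
    distribution with n - 2 degrees of freedom.

    Returns a DataFrame with columns ``metabolite, gene, r, p``.
    """
    if list(metabolites.columns) != list(genes.columns):
        raise ValueError("sample columns differ between metabolite and gene matrices")
    m = _clean_matrix(metabolites, "metabolite")
    g = _clean_matrix(genes, "gene")
    n = m.shape[1]

    def standardize(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        x = x - x.mean(axis=1, keepdims=True)
        return x / np.sqrt((x**2).sum(axis=1, keepdims=True))

    r = standardize(m.to_numpy()) @ standardize(g.to_numpy()).T
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)

    met_ids = np.repeat(m.index.to_numpy(), len(g))
    gene_ids = np.tile(g.index.to_numpy(), len(m))
    return pd.DataFrame(
        {"metabolite": met_ids, "gene": gene_ids, "r": r.ravel(), "p": p.ravel()}
    )


def build_network(
    pairs: pd.DataFrame,
    r_min: float = 0.8,
    fdr_max: float = 0.05,
) -> CoregNetwork:
    """Threshold the pair table into a co-regulation network.

    BH adjustment runs across *all* tested pairs (the full metabolite x gene
    family), then edges with |R| > r_min and FDR < fdr_max are kept. Edge
    weight is |R|; sign is "positive" iff R > 0.
    """
    from .omics import bh_adjust

    if pairs.empty:
        return CoregNetwork()
    required = {"metabolite", "gene", "r", "p"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"pairs table missing columns: {sorted(missing)}")
    fdr = bh_adjust(pairs["p"].to_numpy())
    keep = (np.abs(pairs["r"].to_numpy()) > r_min) & (fdr < fdr_max)
    kept = pairs.loc[keep].copy()
    kept["fdr"] = fdr[keep]
    kept["sign"] = np.where(kept["r"] > 0, "positive", "negative")
    kept["weight"] = kept["r"].abs()
    kept = kept.sort_values(["metabolite", "gene"], kind="stable").reset_index(drop=True)
    return CoregNetwork(edges=kept[EDGE_COLUMNS])


def degree_ranking(net: CoregNetwork) -> pd.DataFrame:
    """Node connectivity table: total, positive and negative degree.

    Sorted by degree descending, ties broken by node id. Columns:
    ``node, kind, degree, positive_degree, negative_degree``.
    """
    if net.n_edges == 0:
        return pd.DataFrame(
            columns=["node", "kind", "degree", "positive_degree", "negative_degree"]
        )
    rows = []
    edges = net.edges
    for kind, col in (("metabolite", "metabolite"), ("gene", "gene")):
        for node, sub in edges.groupby(col):
            pos = int((sub["sign"] == "positive").sum())
            neg = int((sub["sign"] == "negative").sum())
            rows.append((node, kind, pos + neg, pos, neg))
    out = pd.DataFrame(
        rows, columns=["node", "kind", "degree", "positive_degree", "negative_degree"]
    )
    return out.sort_values(
        ["degree", "node"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


# --- export / import -------------------------------------------------------

_GEXF_NS = "http://www.gexf.net/1.2draft"
_EDGE_ATTRS = (("0", "sign"), ("1", "r"), ("2", "p"), ("3", "fdr"))


def export_network(net: CoregNetwork, path: str | Path, fmt: str = "edge-list") -> Path:
    """Write the network to ``path`` as ``edge-list`` CSV or ``gexf``.

    Both writers are deterministic (nodes and edges sorted), so
    export -> read -> export round-trips byte-identically.
    """
    path = Path(path)
    if fmt == "edge-list":
        _write_edge_list(net, path)
    elif fmt == "gexf":
        _write_gexf(net, path)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'edge-list' or 'gexf'")
    return path


def read_network(path: str | Path, fmt: str = "edge-list") -> CoregNetwork:
    """Read a network previously written by :func:`export_network`."""
    path = Path(path)
    if fmt == "edge-list":
        return _read_edge_list(path)
    if fmt == "gexf":
        return _read_gexf(path)
    raise ValueError(f"unknown format {fmt!r}; expected 'edge-list' or 'gexf'")


def _sorted_edges(net: CoregNetwork) -> pd.DataFrame:
    return net.edges.sort_values(["metabolite", "gene"], kind="stable").reset_index(
        drop=True
    )


def _write_edge_list(net: CoregNetwork, path: Path) -> None:
    edges = _sorted_edges(net)
    lines = ["source,target,weight,sign,R,fdr"]
    for row in edges.itertuples(index=False):
        lines.append(
            f"{row.metabolite},{row.gene},{row.weight!r},{row.sign},"
            f"{row.r!r},{row.fdr!r}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_edge_list(path: Path) -> CoregNetwork:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        return CoregNetwork()
    edges = pd.DataFrame(
        {
            "metabolite": df["source"],
            "gene": df["target"],
            "r": df["R"].astype(float),
            # p is not serialized in the edge-list dialect; recover the
            # exact two-sided value from fdr is impossible, keep NaN.
            "p": np.nan,
            "fdr": df["fdr"].astype(float),
            "sign": df["sign"],
            "weight": df["weight"].astype(float),
        }
    )
    return CoregNetwork(edges=edges)


def _write_gexf(net: CoregNetwork, path: Path) -> None:
    edges = _sorted_edges(net)
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<gexf xmlns="{_GEXF_NS}" version="1.2">',
        '  <graph defaultedgetype="undirected">',
        '    <attributes class="node">',
        '      <attribute id="kind" title="kind" type="string" />',
        "    </attributes>",
        '    <attributes class="edge">',
    ]
    for attr_id, title in _EDGE_ATTRS:
        attr_type = "string" if title == "sign" else "double"
        lines.append(
            f'      <attribute id="{attr_id}" title="{title}" type="{attr_type}" />'
        )
    lines.append("    </attributes>")
    lines.append("    <nodes>")
    for kind, nodes in (("metabolite", net.metabolites), ("gene", net.genes)):
        for node in nodes:
            lines.append(f'      <node id="{node}" label="{node}">')
            lines.append(
                f'        <attvalues><attvalue for="kind" value="{kind}" /></attvalues>'
            )
            lines.append("      </node>")
    lines.append("    </nodes>")
    lines.append("    <edges>")
    for i, row in enumerate(edges.itertuples(index=False)):
        lines.append(
            f'      <edge id="{i}" source="{row.metabolite}" target="{row.gene}" '
            f'weight="{row.weight!r}">'
        )
        lines.append("        <attvalues>")
        values = {"sign": row.sign, "r": repr(row.r), "p": repr(row.p), "fdr": repr(row.fdr)}
        for attr_id, title in _EDGE_ATTRS:
            lines.append(
                f'          <attvalue for="{attr_id}" value="{values[title]}" />'
            )
        lines.append("        </attvalues>")
        lines.append("      </edge>")
    lines.append("    </edges>")
    lines.append("  </graph>")
    lines.append("</gexf>")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _read_gexf(path: Path) -> CoregNetwork:
    ns = {"g": _GEXF_NS}
    root = ET.parse(path).getroot()
    kinds = {}
    for node in root.findall(".//g:node", ns):
        attv = node.find(".//g:attvalue[@for='kind']", ns)
        kinds[node.get("id")] = attv.get("value") if attv is not None else None
    rows = []
    for edge in root.findall(".//g:edge", ns):
        source, target = edge.get("source"), edge.get("target")
        if kinds.get(source) != "metabolite" or kinds.get(target) != "gene":
            raise ValueError(f"non-bipartite edge {source!r} -> {target!r} in GEXF")
        raw = {
            attv.get("for"): attv.get("value")
            for attv in edge.findall(".//g:attvalue", ns)
        }
        values = {title: raw[attr_id] for attr_id, title in _EDGE_ATTRS}
        rows.append(
            {
                "metabolite": source,
                "gene": target,
                "r": float(values["r"]),
                "p": float(values["p"]),
                "fdr": float(values["fdr"]),
                "sign": values["sign"],
                "weight": float(edge.get("weight")),
            }
        )
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS) if rows else None
    return CoregNetwork(edges=edges) if edges is not None else CoregNetwork()
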