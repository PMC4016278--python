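"""Co-expression-filtered PPI subnetwork construction and hub ranking.

The interactome is a flat list of unordered gene-symbol pairs. Edges are
(1) restricted to pairs with both endpoints in the expression matrix,
(2) annotated with the Pearson correlation of the two genes' expression
profiles across ALL samples (cases and controls pooled), (3) filtered at
|r| strictly above a threshold (0.8 by default), and (4) mapped onto the
phenotype-related DEG list to give the edge-induced subnetwork whose
high-degree nodes are the candidate hub genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .errors import FormatError, ParameterError

log = logging.getLogger(__name__)

DEFAULT_EDGE_R_THRESHOLD = 0.8


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read a two-column TSV of unordered gene pairs (HPRD-style).

    Pairs are canonicalized (lexicographic), duplicates collapsed, and
    self-loops dropped with a logged count. Malformed lines raise a
    format error naming the line number.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    pairs: list[tuple[str, str]] = []
    n_self = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise FormatError(f"{path}:{lineno}: expected two tab-separated gene ids")
            a, b = fields
            if a == b:
                n_self += 1
                continue
            pairs.append(_canonical(a, b))
    if n_self:
        log.info("read_edge_list: dropped %d self-loops", n_self)
    dedup = sorted(set(pairs))
    if len(dedup) < len(pairs):
        log.info("read_edge_list: collapsed %d duplicate pairs", len(pairs) - len(dedup))
    return pd.DataFrame(dedup, columns=["gene_a", "gene_b"])


def restrict_to_expression(edges: pd.DataFrame, em: ExpressionMatrix) -> pd.DataFrame:
    """Keep edges whose both endpoints are rows of the expression matrix."""
    present = set(em.gene_ids)
    keep = edges["gene_a"].isin(present) & edges["gene_b"].isin(present)
    dropped = int((~keep).sum())
    if dropped:
        log.info("restrict_to_expression: dropped %d edges with absent endpoints", dropped)
    return edges.loc[keep].reset_index(drop=True)


def edge_coexpression(edges: pd.DataFrame, em: ExpressionMatrix) -> pd.DataFrame:
    """Annotate each edge with the Pearson r of its endpoints' profiles.

    Computed across all samples (cases + controls pooled). A zero-variance
    endpoint yields r_edge = 0 (flagged in the log).
    """
    x = em.values.to_numpy()
    idx = {g: i for i, g in enumerate(em.gene_ids)}
    missing = [
        g
        for g in pd.unique(edges[["gene_a", "gene_b"]].to_numpy().ravel())
        if g not in idx
    ]
    if missing:
        raise ParameterError(f"edges reference genes absent from the matrix: {missing[:5]}")
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt((xc**2).sum(axis=1))
    ia = edges["gene_a"].map(idx).to_numpy()
    ib = edges["gene_b"].map(idx).to_numpy()
    denom = norms[ia] * norms[ib]
    num = (xc[ia] * xc[ib]).sum(axis=1)
    r = np.zeros(len(edges))
    ok = denom > 0
    r[ok] = num[ok] / denom[ok]
    if (~ok).any():
        log.warning("edge_coexpression: %d edges with a zero-variance endpoint (r=0)", int((~ok).sum()))
    out = edges.copy()
    out["r_edge"] = np.clip(r, -1.0, 1.0)
    return out


def filter_edges(
    edges: pd.DataFrame, threshold: float = DEFAULT_EDGE_R_THRESHOLD
) -> pd.DataFrame:
    """Keep edges with |r_edge| strictly above the threshold."""
    if "r_edge" not in edges.columns:
        raise ParameterError("edges have no r_edge column; run edge_coexpression first")
    return edges.loc[edges["r_edge"].abs() > threshold].reset_index(drop=True)


@dataclass
class Network:
    """Edge-induced subnetwork with degree-ranked hubs."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def degree(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def edge_table(self) -> pd.DataFrame:
        rows = sorted(
            (_canonical(a, b) + (d.get("r_edge", np.nan),))
            for a, b, d in self.graph.edges(data=True)
        )
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r_edge"])


def build_network(
    edges: pd.DataFrame, pheno_degs: set[str], endpoint_rule: str = "both"
) -> Network:
    """Map phenotype-related DEGs onto the filtered edges.

    ``endpoint_rule="both"`` (default) keeps an edge only when both
    endpoints are phenotype-related DEGs (edge-induced subgraph);
    ``"any"`` keeps edges touching at least one. Nodes are the union of
    surviving edges' endpoints, so every node has degree >= 1.
    """
    if endpoint_rule not in ("both", "any"):
        raise ParameterError(f"unknown endpoint rule {endpoint_rule!r}")
    in_a = edges["gene_a"].isin(pheno_degs)
    in_b = edges["gene_b"].isin(pheno_degs)
    keep = (in_a & in_b) if endpoint_rule == "both" else (in_a | in_b)
    g = nx.Graph()
    for _, row in edges.loc[keep].iterrows():
        g.add_edge(row["gene_a"], row["gene_b"], r_edge=float(row.get("r_edge", np.nan)))
    if g.number_of_edges() == 0:
        log.warning("build_network: no edges survived; empty network")
    return Network(g)


def hub_ranking(net: Network, top_k: int | None = None) -> list[tuple[str, int]]:
    """Nodes ranked by descending degree, ties broken lexicographically."""
    ranked = sorted(net.degree.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked if top_k is None else ranked[:top_k]


def write_network(net: Network, path: str | Path, fmt: str = "sif") -> None:
    """Export as SIF (``gene_a<TAB>pp<TAB>gene_b``) or GraphML.

    GraphML carries per-node degree and per-edge r_edge attributes.
    """
    path = Path(path)
    if fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for _, row in net.edge_table().iterrows():
                fh.write(f"{row['gene_a']}\tpp\t{row['gene_b']}\n")
    elif fmt == "graphml":
        g = net.graph.copy()
        nx.set_node_attributes(g, dict(g.degree()), "degree")
        nx.write_graphml(g, path)
    else:
        raise ParameterError(f"unknown network format {fmt!r}")


def read_sif(path: str | Path) -> Network:
    """Read a SIF file back into a Network (edge attributes not recovered)."""
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 'a<TAB>pp<TAB>b'")
            g.add_edge(fields[0], fields[2])
    return Network(g)
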