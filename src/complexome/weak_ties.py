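"""Edge-level weak-ties analysis (Granovetter).

A weak tie is an edge that carries much shortest-path traffic (high edge
betweenness beta_L) while its endpoints share few neighbors (low
neighborhood overlap O) — the signature of a bridge between otherwise
separate dense regions.  A negative Pearson correlation between O and
beta_L over the edges of a network indicates that such ties are present.

Overlap of an edge (i, j) is

    O_ij = n_ij / ((k_i - 1) + (k_j - 1) - n_ij)

with n_ij the number of common neighbors; it is undefined (NaN) when the
denominator is 0, i.e. for a mutually-pendant edge.  Undefined-O edges are
excluded from the correlation and from weak-tie selection, with a logged
count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .graph_io import InteractionNetwork
from .structural import metric_correlation

logger = logging.getLogger(__name__)


def _graph(net) -> nx.Graph:
    return net.graph if isinstance(net, InteractionNetwork) else net


@dataclass
class WeakTieReport:
    """Ranked per-edge table plus the selected weak-tie edges and nodes."""

    table: pd.DataFrame  # columns: protein_a, protein_b, beta_L, overlap, weak_tie
    edges: list[tuple]
    nodes: set


def edge_betweenness(net) -> dict[frozenset, float]:
    """Unnormalized edge betweenness beta_L over unordered node pairs.

    beta_L(e) = sum over pairs {v,w} of sigma_vw(e) / sigma_vw, where
    sigma_vw counts shortest v-w paths and sigma_vw(e) those through e.
    """
    g = _graph(net)
    eb = nx.edge_betweenness_centrality(g, normalized=False)
    return {frozenset(e): v for e, v in eb.items()}


def neighborhood_overlap(net) -> dict[frozenset, float]:
    """Per-edge neighborhood overlap O_ij (NaN where undefined)."""
    g = _graph(net)
    out: dict[frozenset, float] = {}
    for u, v in g.edges():
        nu, nv = set(g.neighbors(u)), set(g.neighbors(v))
        n_common = len((nu & nv) - {u, v})
        denom = (g.degree(u) - 1) + (g.degree(v) - 1) - n_common
        out[frozenset((u, v))] = n_common / denom if denom > 0 else float("nan")
    return out


def edge_metrics(net) -> pd.DataFrame:
    """Tidy per-edge table: protein_a, protein_b, beta_L, overlap."""
    bl = edge_betweenness(net)
    ov = neighborhood_overlap(net)
    rows = []
    for e in bl:
        u, v = sorted(e, key=str)
        rows.append({"protein_a": u, "protein_b": v, "beta_L": bl[e], "overlap": ov[e]})
    frame = pd.DataFrame(rows, columns=["protein_a", "protein_b", "beta_L", "overlap"])
    return frame.sort_values("beta_L", ascending=False, ignore_index=True)


def overlap_betweenness_correlation(net) -> float:
    """Pearson correlation of O_ij and beta_L over edges with defined O.

    A negative value indicates weak ties: high-traffic edges tend to join
    endpoints with little shared neighborhood.  NaN if fewer than 3 defined
    edges or zero variance.
    """
    bl = edge_betweenness(net)
    ov = neighborhood_overlap(net)
    pairs = [(ov[e], bl[e]) for e in bl if not np.isnan(ov[e])]
    n_undef = len(bl) - len(pairs)
    if n_undef:
        logger.info("overlap_betweenness_correlation: %d edge(s) with undefined O excluded", n_undef)
    if len(pairs) < 3:
        return float("nan")
    o, b = zip(*pairs)
    try:
        return metric_correlation(o, b)
    except ValueError:
        return float("nan")


def extract_weak_ties(
    net,
    beta_quantile: float = 0.9,
    overlap_quantile: float = 0.1,
) -> WeakTieReport:
    """Select edges with beta_L >= its ``beta_quantile`` AND O <= its
    ``overlap_quantile`` (quantiles taken over defined-O edges only).

    An empty selection is a valid result, not an error.  The full ranked
    edge table is always returned so the thresholding is transparent.
    """
    if not (0.0 < beta_quantile < 1.0 and 0.0 < overlap_quantile < 1.0):
        raise ValueError("quantiles must lie in (0, 1)")
    table = edge_metrics(net)
    defined = table.dropna(subset=["overlap"])
    # degenerate case: if neither metric varies, no edge is distinguished
    # ("high beta_L / low O" is meaningless, e.g. in a complete graph)
    if len(defined) == 0 or (defined["beta_L"].nunique() == 1
                             and defined["overlap"].nunique() == 1):
        table = table.assign(weak_tie=False)
        return WeakTieReport(table=table, edges=[], nodes=set())
    b_thr = float(np.quantile(defined["beta_L"], beta_quantile))
    o_thr = float(np.quantile(defined["overlap"], overlap_quantile))
    flag = (table["beta_L"] >= b_thr) & (table["overlap"] <= o_thr)
    flag &= table["overlap"].notna()
    table = table.assign(weak_tie=flag)
    picked = table[table["weak_tie"]]
    edges = [tuple(sorted((a, b), key=str))
             for a, b in zip(picked["protein_a"], picked["protein_b"])]
    nodes = set(picked["protein_a"]) | set(picked["protein_b"])
    return WeakTieReport(table=table, edges=edges, nodes=nodes)
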