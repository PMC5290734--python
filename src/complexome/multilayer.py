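"""Multilayer (cross-layer) analysis of a normal/disease network family.

"Multilayer" here is set arithmetic over layers plus per-layer analysis of
the shared nodes: proteins present in *every* layer of a condition form the
condition's common set; the subtractive analysis then counts, per layer,
the interactions among common proteins (IN connections) and from common
proteins outward (OUT connections), compares the common subset's clustering
with the whole layer, and screens for structurally exceptional nodes —
high-betweenness/low-degree connectors and weak-tie endpoints — that recur
across layers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import structural, weak_ties
from .graph_io import DISEASE, NORMAL, InteractionNetwork, LayerFamily

logger = logging.getLogger(__name__)


@dataclass
class CommonSetReport:
    """Cross-layer common node sets and their Venn counts.

    ``common_both`` is the intersection of the two per-condition common
    sets; the union is also exposed (``union_normal_disease``) since both
    readings of "common to normal and disease" occur in practice.
    """

    common_disease: set
    common_normal: set

    @property
    def common_both(self) -> set:
        return self.common_disease & self.common_normal

    @property
    def union_normal_disease(self) -> set:
        return self.common_disease | self.common_normal

    @property
    def venn_counts(self) -> tuple[int, int, int]:
        return len(self.common_disease), len(self.common_normal), len(self.common_both)


@dataclass
class SubtractiveReport:
    """Per-layer IN/OUT connection counts and subset clustering ratio."""

    layer: str
    in_connections: int
    out_degree: dict
    mean_out_degree: float
    mean_degree: float
    out_to_mean_degree_ratio: float
    clustering_ratio: float


@dataclass
class CandidateReport:
    """Cross-layer candidates and the per-layer evidence behind them."""

    candidates: set
    evidence: pd.DataFrame  # node x per-layer screen/weak-tie columns
    screened_per_layer: dict[str, set] = field(default_factory=dict)
    weak_tie_nodes_per_layer: dict[str, set] = field(default_factory=dict)


def common_nodes(family: LayerFamily) -> CommonSetReport:
    """Strict intersection of node sets per condition, and across conditions."""
    disease = family.by_condition(DISEASE)
    normal = family.by_condition(NORMAL)
    if not disease or not normal:
        raise ValueError("family must contain at least one layer per condition")
    common_d = set.intersection(*(net.nodes for net in disease.values()))
    common_n = set.intersection(*(net.nodes for net in normal.values()))
    return CommonSetReport(common_disease=common_d, common_normal=common_n)


def in_out_connections(
    layer: InteractionNetwork, common: set
) -> tuple[int, dict, float]:
    """IN/OUT connection counts of a common set within one layer.

    IN counts edges with both endpoints in the common set (once per edge);
    OUT is, per common node, the number of edges to non-common nodes.
    Common nodes absent from the layer are logged and dropped.  Returns
    (IN, per-node OUT, mean OUT / layer mean degree).
    """
    common = set(common)
    if not common:
        raise ValueError("empty common set")
    g = layer.graph
    missing = common - set(g.nodes)
    if missing:
        logger.info("in_out_connections(%s): %d common node(s) absent, dropped",
                    layer.name, len(missing))
        common -= missing
    if not common:
        raise ValueError("no common node present in layer")
    in_count = 0
    out_degree = {v: 0 for v in common}
    for u, v in g.edges():
        u_in, v_in = u in common, v in common
        if u_in and v_in:
            in_count += 1
        elif u_in:
            out_degree[u] += 1
        elif v_in:
            out_degree[v] += 1
    mean_k = 2.0 * g.number_of_edges() / g.number_of_nodes()
    mean_out = float(np.mean(list(out_degree.values())))
    ratio = mean_out / mean_k if mean_k > 0 else float("nan")
    return in_count, out_degree, ratio


def subset_clustering_ratio(
    layer: InteractionNetwork, common: set, induced: bool = False
) -> float:
    """<CC> over the common nodes divided by the whole-layer <CC>.

    By default each node's CC is computed in the FULL layer and averaged
    over the common subset (the subset is profiled in situ); with
    ``induced=True`` the numerator instead uses the induced subgraph of the
    common set.  NaN when the whole-layer <CC> is 0.
    """
    common = set(common) & layer.nodes
    if not common:
        raise ValueError("empty common set (after restriction to layer nodes)")
    cc, mean_cc = structural.clustering_coefficients(layer)
    if mean_cc == 0 or np.isnan(mean_cc):
        return float("nan")
    if induced:
        sub = InteractionNetwork(layer.graph.subgraph(common).copy())
        _cc_sub, subset_mean = structural.clustering_coefficients(sub)
    else:
        subset_mean = float(np.mean([cc[v] for v in common]))
    return subset_mean / mean_cc


def subtractive_report(layer: InteractionNetwork, common: set) -> SubtractiveReport:
    in_count, out_deg, ratio = in_out_connections(layer, common)
    mean_k = 2.0 * layer.n_edges / layer.n_nodes
    return SubtractiveReport(
        layer=layer.name,
        in_connections=in_count,
        out_degree=out_deg,
        mean_out_degree=float(np.mean(list(out_deg.values()))),
        mean_degree=mean_k,
        out_to_mean_degree_ratio=ratio,
        clustering_ratio=subset_clustering_ratio(layer, common),
    )


def screen_high_bc_low_k(
    layer: InteractionNetwork,
    bc_quantile: float = 0.9,
    k_quantile: float = 0.5,
    restrict_to: set | None = None,
) -> set:
    """Nodes with betweenness >= its ``bc_quantile`` and degree <= its
    ``k_quantile`` (quantiles over all layer nodes), optionally intersected
    with ``restrict_to`` (e.g. the disease common set)."""
    if not (0.0 < bc_quantile < 1.0 and 0.0 < k_quantile < 1.0):
        raise ValueError("quantiles must lie in (0, 1)")
    g = layer.graph
    if g.number_of_nodes() == 0:
        return set()
    bc = structural.betweenness_centrality(layer)
    nodes = list(g.nodes)
    bc_vec = np.array([bc[v] for v in nodes])
    k_vec = np.array([g.degree(v) for v in nodes], dtype=float)
    if bc_vec.max() == bc_vec.min():
        return set()  # no node is distinguished (e.g. complete graph)
    bc_thr = float(np.quantile(bc_vec, bc_quantile))
    k_thr = float(np.quantile(k_vec, k_quantile))
    picked = {v for v, b, k in zip(nodes, bc_vec, k_vec) if b >= bc_thr and k <= k_thr}
    if restrict_to is not None:
        picked &= set(restrict_to)
    return picked


def rank_candidates(
    family: LayerFamily,
    common: set,
    min_layers_bc: int = 4,
    require_weak_tie: bool = True,
    bc_quantile: float = 0.9,
    k_quantile: float = 0.5,
    beta_quantile: float = 0.9,
    overlap_quantile: float = 0.1,
    condition: str = DISEASE,
) -> CandidateReport:
    """Cross-layer candidate proteins: common nodes that pass the
    high-betweenness/low-degree screen in at least ``min_layers_bc`` layers
    of ``condition`` and (optionally) touch an extracted weak tie in at
    least one of them.

    The full per-layer evidence table is always emitted.
    """
    common = set(common)
    if not common:
        raise ValueError("empty common set")
    layers = family.by_condition(condition)
    screened: dict[str, set] = {}
    wt_nodes: dict[str, set] = {}
    for tissue, layer in sorted(layers.items()):
        screened[tissue] = screen_high_bc_low_k(
            layer, bc_quantile=bc_quantile, k_quantile=k_quantile, restrict_to=common
        )
        report = weak_ties.extract_weak_ties(
            layer, beta_quantile=beta_quantile, overlap_quantile=overlap_quantile
        )
        wt_nodes[tissue] = report.nodes & common
    n_pass = {v: sum(v in s for s in screened.values()) for v in common}
    n_wt = {v: sum(v in s for s in wt_nodes.values()) for v in common}
    candidates = {v for v in common if n_pass[v] >= min_layers_bc}
    if require_weak_tie:
        candidates = {v for v in candidates if n_wt[v] >= 1}
    rows = []
    for v in sorted(common, key=str):
        row = {"protein": str(v), "n_layers_screened": n_pass[v], "n_layers_weak_tie": n_wt[v],
               "candidate": v in candidates}
        for tissue in sorted(layers):
            row[f"screen_{tissue}"] = v in screened[tissue]
            row[f"weak_tie_{tissue}"] = v in wt_nodes[tissue]
        rows.append(row)
    evidence = pd.DataFrame(rows).sort_values(
        ["candidate", "n_layers_screened", "n_layers_weak_tie", "protein"],
        ascending=[False, False, False, True], ignore_index=True,
    )
    return CandidateReport(
        candidates=candidates, evidence=evidence,
        screened_per_layer=screened, weak_tie_nodes_per_layer=wt_nodes,
    )


def join_annotations(evidence: pd.DataFrame, annotations: dict[str, str]) -> pd.DataFrame:
    """Join a user-supplied protein -> label mapping (e.g. sensor/effector)
    onto a candidate evidence table, verbatim."""
    out = evidence.copy()
    out["annotation"] = out["protein"].map(annotations).fillna("")
    return out
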