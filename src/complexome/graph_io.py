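"""Reading, writing and assembling protein-protein interaction networks.

A master interactome (e.g. a STRING-style confidence-scored edge list) is
filtered by confidence and then sliced into per-tissue, per-condition layers
as *induced subgraphs*: every layer inherits its interactions from the same
master network, so differences between a normal and a disease layer arise
only from the proteins present, never from re-scored edges.

Protein identifiers are opaque, case-sensitive strings; no identifier
normalization or species mapping is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

NORMAL = "normal"
DISEASE = "disease"
CONDITIONS = (NORMAL, DISEASE)


class EdgeListFormatError(ValueError):
    """Raised for malformed rows or out-of-range confidences in edge lists."""


@dataclass
class InteractionNetwork:
    """An undirected, simple protein-protein interaction network.

    Wraps a :class:`networkx.Graph` whose nodes are protein identifiers.
    Invariants: no self-loops, no parallel edges, every edge endpoint is a
    node of the graph (all guaranteed by the networkx simple-graph model and
    the constructors in this module).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    name: str = ""

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set:
        return {frozenset(e) for e in self.graph.edges}

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def copy(self, name: str | None = None) -> "InteractionNetwork":
        return InteractionNetwork(self.graph.copy(), self.name if name is None else name)


@dataclass
class WeightedInteractome:
    """A confidence-weighted interactome; each edge carries a score in [0, 1]."""

    graph: nx.Graph = field(default_factory=nx.Graph)
    name: str = ""

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class LayerFamily:
    """A collection of networks indexed by (tissue, condition).

    ``condition`` is restricted to the two-level factor ``{"normal",
    "disease"}``; layer keys are unique by construction of the mapping.
    """

    layers: dict[tuple[str, str], InteractionNetwork] = field(default_factory=dict)

    def add(self, tissue: str, condition: str, net: InteractionNetwork) -> None:
        if condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
        self.layers[(tissue, condition)] = net

    def by_condition(self, condition: str) -> dict[str, InteractionNetwork]:
        if condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
        return {t: n for (t, c), n in self.layers.items() if c == condition}

    @property
    def tissues(self) -> list[str]:
        return sorted({t for (t, _c) in self.layers})

    def __len__(self) -> int:
        return len(self.layers)

    def items(self):
        return self.layers.items()


def read_edge_list(
    path: str | Path,
    delimiter: str = "\t",
    has_confidence: bool | None = None,
    string_scores: bool = False,
) -> WeightedInteractome | InteractionNetwork:
    """Read an edge list (``protein_a  protein_b  [confidence]``).

    ``#``-prefixed lines are comments.  Self-loops are dropped (count
    logged); duplicate pairs are collapsed keeping the maximum confidence.
    With ``string_scores=True`` integer scores in [0, 1000] (the STRING
    ``combined_score`` dialect) are rescaled by /1000.

    ``has_confidence=None`` auto-detects from the first data row.
    Returns a :class:`WeightedInteractome` when confidences are present,
    otherwise an :class:`InteractionNetwork`.
    """
    path = Path(path)
    graph = nx.Graph()
    n_self_loops = 0
    n_rows = 0
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(delimiter) if delimiter != " " else line.split()
        if len(parts) < 2:
            raise EdgeListFormatError(f"malformed row (need >=2 columns), line {lineno}")
        u, v = parts[0].strip(), parts[1].strip()
        if not u or not v:
            raise EdgeListFormatError(f"empty protein identifier, line {lineno}")
        if has_confidence is None:
            has_confidence = len(parts) >= 3
        conf = None
        if has_confidence:
            if len(parts) < 3:
                raise EdgeListFormatError(f"missing confidence column, line {lineno}")
            try:
                conf = float(parts[2])
            except ValueError as exc:
                raise EdgeListFormatError(f"unparseable confidence, line {lineno}") from exc
            if string_scores:
                conf /= 1000.0
            if not 0.0 <= conf <= 1.0:
                raise EdgeListFormatError(f"confidence out of range, line {lineno}")
        n_rows += 1
        if u == v:
            n_self_loops += 1
            continue
        if conf is None:
            graph.add_edge(u, v)
        elif not graph.has_edge(u, v) or graph.edges[u, v]["confidence"] < conf:
            graph.add_edge(u, v, confidence=conf)
    if n_self_loops:
        logger.info("read_edge_list(%s): dropped %d self-loop(s)", path.name, n_self_loops)
    if n_rows == 0:
        logger.warning("read_edge_list(%s): empty edge list", path.name)
    if has_confidence:
        return WeightedInteractome(graph, name=path.stem)
    return InteractionNetwork(graph, name=path.stem)


def filter_by_confidence(
    net: WeightedInteractome,
    threshold: float = 0.50,
    keep_isolates: bool = False,
) -> InteractionNetwork:
    """Keep edges with confidence *strictly greater* than ``threshold``.

    Nodes left without any retained edge are dropped unless
    ``keep_isolates`` is set.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    out = nx.Graph()
    if keep_isolates:
        out.add_nodes_from(net.graph.nodes)
    for u, v, data in net.graph.edges(data=True):
        if data["confidence"] > threshold:
            out.add_edge(u, v)
    return InteractionNetwork(out, name=net.name)


def build_layer(
    proteins: Iterable[str],
    interactome: InteractionNetwork,
    tissue: str = "",
    condition: str = "",
) -> InteractionNetwork:
    """Induce a condition layer on ``proteins`` from the master interactome.

    An edge (u, v) is in the layer iff both endpoints are in ``proteins``
    and the edge exists in the interactome.  Proteins absent from the
    interactome are retained as isolated nodes (their count is logged) so
    that the layer's N counts proteins, not only connected ones.
    """
    proteins = set(proteins)
    if not proteins:
        raise ValueError("empty protein set")
    present = proteins & set(interactome.graph.nodes)
    sub = nx.Graph(interactome.graph.subgraph(present))
    missing = proteins - present
    sub.add_nodes_from(missing)
    if missing:
        logger.info(
            "build_layer(%s,%s): %d protein(s) absent from interactome, kept as isolates",
            tissue, condition, len(missing),
        )
    label = f"{tissue}_{condition}" if tissue or condition else "layer"
    return InteractionNetwork(sub, name=label)


def read_protein_list(path: str | Path) -> set[str]:
    """Read a plain-text protein list, one identifier per line; '#' comments skipped."""
    out = set()
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def write_network(net: InteractionNetwork, path: str | Path, format: str = "tsv") -> None:
    """Write a network as an edge-list TSV (isolates in a trailing block) or GraphML.

    Round-trips losslessly: ``read_network(write_network(net)) == net`` on
    (node set, edge set), including unicode identifiers and isolated nodes.
    """
    path = Path(path)
    if format == "tsv":
        lines = ["#protein_a\tprotein_b"]
        for u, v in sorted((sorted(map(str, e)) for e in net.graph.edges)):
            lines.append(f"{u}\t{v}")
        isolates = sorted(str(n) for n in nx.isolates(net.graph))
        for n in isolates:
            lines.append(f"#isolate\t{n}")
        path.write_text("\n".join(lines) + "\n")
    elif format == "graphml":
        nx.write_graphml(net.graph, path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'graphml')")


def read_network(path: str | Path, format: str = "tsv") -> InteractionNetwork:
    """Inverse of :func:`write_network`."""
    path = Path(path)
    if format == "tsv":
        graph = nx.Graph()
        for raw in path.read_text().splitlines():
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#isolate\t"):
                graph.add_node(line.split("\t", 1)[1])
                continue
            if line.startswith("#"):
                continue
            u, v = line.split("\t")[:2]
            graph.add_edge(u, v)
        return InteractionNetwork(graph, name=path.stem)
    if format == "graphml":
        return InteractionNetwork(nx.Graph(nx.read_graphml(path)), name=path.stem)
    raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'graphml')")


def family_from_manifest(
    manifest: Mapping, base_dir: str | Path = "."
) -> LayerFamily:
    """Build a LayerFamily from a manifest mapping.

    Expected structure (typically loaded from YAML)::

        interactome: edges.tsv          # optional master edge list
        confidence_threshold: 0.5       # applied when scores present
        layers:
          - {tissue: breast, condition: disease, proteins: breast_disease.txt}
          - {tissue: breast, condition: disease, edges: breast_disease_edges.tsv}

    A layer gives either a protein list (induced from the interactome) or a
    pre-built edge list.
    """
    base = Path(base_dir)
    interactome: InteractionNetwork | None = None
    if manifest.get("interactome"):
        net = read_edge_list(base / manifest["interactome"])
        if isinstance(net, WeightedInteractome):
            net = filter_by_confidence(net, float(manifest.get("confidence_threshold", 0.50)))
        interactome = net
    family = LayerFamily()
    for spec in manifest.get("layers", []):
        tissue, condition = spec["tissue"], spec["condition"]
        if "edges" in spec:
            layer = read_network(base / spec["edges"])
            layer.name = f"{tissue}_{condition}"
        elif "proteins" in spec:
            if interactome is None:
                raise ValueError("layer gives a protein list but manifest has no interactome")
            proteins = read_protein_list(base / spec["proteins"])
            layer = build_layer(proteins, interactome, tissue, condition)
        else:
            raise ValueError(f"layer {tissue}/{condition}: needs 'edges' or 'proteins'")
        family.add(tissue, condition, layer)
    return family
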