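"""Synthetic multilayer PPI families with planted ground truth.

Real interactomes are heavy-tailed, highly clustered, rich in exact
duplicate nodes (a spectral fingerprint of gene duplication), and organized
into modules bridged by weak ties.  This module grows a master interactome
by duplication-divergence — duplicate a random progenitor, keep each
inherited interaction with probability ``retention``, occasionally keep all
of them (an exact duplicate), and cross-link duplicate to progenitor with
probability ``cross_link`` — and then slices it into T tissues x
{normal, disease} layers as induced subgraphs over sampled node sets.

Planted structures, all recorded in :class:`GroundTruth`:

* a common set present in every disease layer, one in every normal layer,
  and their overlap, with configurable Venn sizes (defaults 63/19/8);
* bridge edges joining distant, neighborhood-disjoint regions (expected to
  surface as weak ties: high edge betweenness, near-zero overlap);
* connector nodes of low degree wired to high-degree anchors in mutually
  distant regions (expected to surface in the high-betweenness/low-degree
  screen) — the planted analogue of "sensor" proteins;
* exact duplicate node pairs (cloned neighborhoods), feeding the
  zero-eigenvalue analysis.

Accidental commonality is removed: any node outside a planted common set
that happens to appear in every layer of a condition is deleted from one
randomly chosen layer, so the planted Venn structure is recovered exactly
by construction, not just with high probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .graph_io import DISEASE, NORMAL, InteractionNetwork, LayerFamily


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic family generator.

    Defaults are the package's reference conditions: a 500-protein master
    built from 10 duplication-divergence modules (retention 0.55,
    cross-link 0.85, 10% exact duplications) on a sparse ring backbone.
    Subcritical retention keeps the network sparse (mean degree near 8);
    the frequent duplicate-progenitor cross-links make low-degree nodes
    highly clustered, so the degree-clustering correlation is negative as
    in hierarchical PPI networks; the modular ring keeps the diameter well
    above an ER match.  7 tissues are sampled at fraction 0.6 per layer,
    with planted common sets of sizes 63 (disease), 19 (normal), 8 (both),
    5 bridges, 6 three-anchor connectors and 5 cloned duplicate pairs.
    """

    n_interactome: int = 500
    retention: float = 0.55         # probability an inherited edge survives divergence
    cross_link: float = 0.85        # probability of a duplicate-progenitor edge
    exact_duplicate_fraction: float = 0.10  # duplications that keep ALL edges
    n_modules: int = 10             # DD modules on the ring backbone
    backbone_edges: int = 2         # edges joining each ring-adjacent module pair
    n_tissues: int = 7
    sampling_fraction: float = 0.6  # per-layer inclusion probability of non-planted nodes
    n_common_disease: int = 63
    n_common_normal: int = 19
    n_common_both: int = 8
    n_bridges: int = 5
    n_connectors: int = 6
    connector_anchors: int = 3      # anchors, one per distinct module, per connector
    n_duplicate_pairs: int = 5      # cloned exact-duplicate pairs appended at the end
    seed: int = 0

    def validate(self) -> None:
        for name in ("retention", "cross_link", "exact_duplicate_fraction",
                     "sampling_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.n_common_both > min(self.n_common_disease, self.n_common_normal):
            raise ValueError("n_common_both exceeds a per-condition common-set size")
        planted = self.n_common_disease + self.n_common_normal - self.n_common_both
        if planted > self.n_interactome:
            raise ValueError("planted common sets exceed the interactome size")
        if self.n_tissues < 1:
            raise ValueError("need at least one tissue")
        if self.n_modules < 3:
            raise ValueError("need at least 3 modules for a ring backbone")
        if self.n_interactome < 5 * self.n_modules:
            raise ValueError("n_interactome too small for the module count")
        if self.backbone_edges < 1:
            raise ValueError("backbone_edges must be >= 1")


@dataclass
class GroundTruth:
    """Planted structures of a synthetic family."""

    common_disease: set
    common_normal: set
    bridge_edges: list[tuple[str, str]]
    connectors: list[str]
    connector_anchors: dict[str, list[str]]
    duplicate_pairs: list[tuple[str, str]]
    layer_nodes: dict[tuple[str, str], set] = field(default_factory=dict)
    master: "InteractionNetwork | None" = None  # interactome incl. planted structures

    @property
    def common_both(self) -> set:
        return self.common_disease & self.common_normal

    def to_json(self, path: str | Path) -> None:
        payload = {
            "common_disease": sorted(self.common_disease),
            "common_normal": sorted(self.common_normal),
            "common_both": sorted(self.common_both),
            "bridge_edges": [list(e) for e in self.bridge_edges],
            "connectors": list(self.connectors),
            "connector_anchors": {k: list(v) for k, v in self.connector_anchors.items()},
            "duplicate_pairs": [list(p) for p in self.duplicate_pairs],
            "layer_nodes": {f"{t}|{c}": sorted(v) for (t, c), v in self.layer_nodes.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _node(i: int) -> str:
    return f"P{i:05d}"


def _grow_dd_module(
    size: int, config: "SyntheticConfig", rng: np.random.Generator, first_id: int
) -> tuple[nx.Graph, int]:
    """Grow one duplication-divergence module of ``size`` nodes.

    Starts from a 5-clique and adds nodes one at a time: pick a progenitor
    uniformly, inherit each of its edges with probability ``retention`` (or
    all of them, with probability ``exact_duplicate_fraction`` — an exact
    duplicate), and add the duplicate-progenitor cross-link with
    probability ``cross_link``.  A duplicate that inherits nothing is
    attached to its progenitor, so modules have no isolates.
    """
    g = nx.complete_graph(5)
    g = nx.relabel_nodes(g, {i: _node(first_id + i) for i in range(5)})
    next_id = first_id + 5
    while g.number_of_nodes() < size:
        progenitor = str(rng.choice(sorted(g.nodes)))
        new = _node(next_id)
        next_id += 1
        nbrs = sorted(g.neighbors(progenitor))
        if rng.random() < config.exact_duplicate_fraction:
            kept = nbrs
        else:
            kept = [v for v in nbrs if rng.random() < config.retention]
        g.add_node(new)
        for v in kept:
            g.add_edge(new, v)
        if rng.random() < config.cross_link:
            g.add_edge(new, progenitor)
        if g.degree(new) == 0:
            g.add_edge(new, progenitor)
    return g, next_id


def _generate_modular(
    config: "SyntheticConfig", rng: np.random.Generator
) -> tuple[nx.Graph, list[list[str]]]:
    """Assemble the master interactome: DD modules on a sparse ring backbone.

    Each module is an independently grown duplication-divergence graph;
    ring-adjacent modules are joined by ``backbone_edges`` random edges.
    The modular organization concentrates inter-module traffic on few
    edges, which is what makes planted bridges and connectors stand out.
    """
    sizes = [config.n_interactome // config.n_modules] * config.n_modules
    sizes[0] += config.n_interactome - sum(sizes)
    g = nx.Graph()
    modules: list[list[str]] = []
    next_id = 0
    for size in sizes:
        mod, next_id = _grow_dd_module(size, config, rng, next_id)
        g.update(mod)
        modules.append(sorted(mod.nodes))
    m = config.n_modules
    for i in range(m):
        a, b = modules[i], modules[(i + 1) % m]
        for _ in range(config.backbone_edges):
            g.add_edge(str(rng.choice(a)), str(rng.choice(b)))
    return g, modules


def generate_interactome(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> InteractionNetwork:
    """Generate a duplication-divergence master interactome.

    The graph is a ring of independently grown DD modules (see
    :func:`_grow_dd_module`): heavy-tailed degrees, high clustering and
    exact duplicate nodes within modules, sparse backbone edges between
    them.  Module membership is stored in ``graph.graph['modules']``.
    Deterministic under the seed.
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    g, modules = _generate_modular(config, rng)
    g.graph["modules"] = modules
    return InteractionNetwork(g, name="synthetic_interactome")


def _ring_distance(i: int, j: int, m: int) -> int:
    return min(abs(i - j), m - abs(i - j))


def _assign_module_groups(
    n_modules: int, n_connectors: int, group_size: int, n_bridges: int
) -> tuple[list[tuple[int, ...]], list[tuple[int, int]]]:
    """Pick module groups for connectors and module pairs for bridges.

    Every connector gets ``group_size`` pairwise non-adjacent modules and
    every bridge a non-adjacent module pair, with no unordered module pair
    reused across any plant — each planted shortcut is therefore the unique
    direct route between the modules it joins.  Greedy, deterministic.
    """
    from itertools import combinations

    used: set[frozenset] = set()
    groups: list[tuple[int, ...]] = []
    for _ in range(n_connectors):
        best, best_score = None, -1
        for combo in combinations(range(n_modules), group_size):
            pairs = [frozenset(p) for p in combinations(combo, 2)]
            dists = [_ring_distance(*sorted(p), n_modules) for p in pairs]
            if min(dists) < 2 or any(p in used for p in pairs):
                continue
            score = sum(dists)
            if score > best_score:
                best, best_score = combo, score
        if best is None:
            raise ValueError(
                "cannot place connectors without reusing a module pair; "
                "reduce n_connectors/connector_anchors or raise n_modules"
            )
        groups.append(best)
        used |= {frozenset(p) for p in combinations(best, 2)}
    bridge_pairs: list[tuple[int, int]] = []
    candidates = sorted(
        (p for p in combinations(range(n_modules), 2)
         if _ring_distance(*p, n_modules) >= 2 and frozenset(p) not in used),
        key=lambda p: (-_ring_distance(*p, n_modules), p),
    )
    if len(candidates) < n_bridges:
        raise ValueError("not enough unused module pairs for the requested bridges")
    bridge_pairs = candidates[:n_bridges]
    return groups, bridge_pairs


def generate_layer_family(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[LayerFamily, GroundTruth]:
    """Generate a T x {normal, disease} family with planted ground truth.

    Pipeline: grow the modular interactome; append cloned duplicate pairs;
    wire in connector nodes (low degree, anchored in distinct distant
    modules); add bridge edges between neighborhood-disjoint nodes of
    non-adjacent modules; choose the planted common sets (connectors,
    anchors and bridge endpoints are folded into the disease common set so
    they persist across all disease layers); sample the remaining nodes
    into each layer and enforce Venn exactness.
    """
    config = config or SyntheticConfig()
    config.validate()
    master_seed = config.seed if seed is None else seed
    rng = np.random.default_rng(master_seed)

    g, modules = _generate_modular(config, rng)
    next_id = config.n_interactome
    degs = dict(g.degree())

    # Cloned exact-duplicate pairs (guaranteed identical neighborhoods).
    duplicate_pairs: list[tuple[str, str]] = []
    eligible = [v for v in sorted(g.nodes) if 2 <= g.degree(v) <= 20]
    originals = rng.choice(eligible, size=min(config.n_duplicate_pairs, len(eligible)),
                           replace=False)
    for orig in originals:
        clone = _node(next_id)
        next_id += 1
        g.add_node(clone)
        for v in list(g.neighbors(orig)):
            g.add_edge(clone, v)
        duplicate_pairs.append((str(orig), clone))

    # Assign mutually distant module groups to connectors and the remaining
    # non-adjacent module pairs to bridges, with no module pair reused, so
    # every planted shortcut is the unique direct route between its modules.
    conn_groups, bridge_mod_pairs = _assign_module_groups(
        config.n_modules, config.n_connectors, config.connector_anchors,
        config.n_bridges,
    )

    def _top_degree_node(module_idx: int, exclude: set) -> str:
        members = [v for v in modules[module_idx] if v not in exclude]
        members.sort(key=lambda v: (-degs[v], v))
        return members[0]

    # Connector ("sensor") nodes: low degree, anchored to a high-degree hub
    # in each module of their group -> they carry the traffic between those
    # modules and acquire high betweenness.
    connectors: list[str] = []
    connector_anchors: dict[str, list[str]] = {}
    used_anchors: set = set()
    for group in conn_groups:
        anchors = []
        for mod in group:
            a = _top_degree_node(mod, used_anchors)
            used_anchors.add(a)
            anchors.append(a)
        conn = _node(next_id)
        next_id += 1
        g.add_node(conn)
        for a in anchors:
            g.add_edge(conn, a)
        connectors.append(conn)
        connector_anchors[conn] = anchors

    # Bridge edges: join high-degree, neighborhood-disjoint nodes of two
    # non-adjacent modules.  High degree keeps the endpoints well embedded
    # in every sampled layer (so the bridge is a tie between dense regions,
    # not a pendant link) and distinguishes them from the low-degree
    # connector nodes.
    deg_cut = float(np.quantile(list(degs.values()), 0.7))
    bridge_edges: list[tuple[str, str]] = []
    used_bridge: set = set(used_anchors)
    for (mi, mj) in bridge_mod_pairs:
        cand_i = [v for v in modules[mi] if degs[v] >= deg_cut and v not in used_bridge]
        cand_j = [v for v in modules[mj] if degs[v] >= deg_cut and v not in used_bridge]
        rng.shuffle(cand_i)
        rng.shuffle(cand_j)
        u, v = None, None
        for ui in cand_i:
            vj = next((w for w in cand_j
                       if not (set(g.neighbors(ui)) & set(g.neighbors(w)))), None)
            if vj is not None:
                u, v = ui, vj
                break
        if u is None:
            raise RuntimeError("could not place a bridge between modules "
                               f"{mi} and {mj}")
        g.add_edge(u, v)
        bridge_edges.append((u, v))
        used_bridge |= {u, v}

    # Planted common sets.  Structural plants live in the disease common set
    # so every disease layer retains them.
    anchor_nodes = [a for anchors in connector_anchors.values() for a in anchors]
    bridge_nodes = [x for e in bridge_edges for x in e]
    forced_d = list(dict.fromkeys(connectors + anchor_nodes + bridge_nodes))
    if len(forced_d) > config.n_common_disease:
        raise ValueError("planted structures exceed the disease common-set size")
    pool = [v for v in sorted(g.nodes) if v not in set(forced_d)]
    rng.shuffle(pool)
    n_fill_d = config.n_common_disease - len(forced_d)
    fill_d = pool[:n_fill_d]
    common_d = set(forced_d) | set(fill_d)
    both = set(rng.choice(sorted(fill_d), size=config.n_common_both, replace=False))
    rest = [v for v in pool[n_fill_d:]]
    common_n = both | set(rest[: config.n_common_normal - config.n_common_both])

    # Per-layer node sets: planted commons plus a Bernoulli sample of the rest.
    all_nodes = sorted(g.nodes)
    tissues = [f"tissue{i + 1}" for i in range(config.n_tissues)]
    layer_nodes: dict[tuple[str, str], set] = {}
    for cond, planted in ((DISEASE, common_d), (NORMAL, common_n)):
        for t in tissues:
            extra = {v for v in all_nodes
                     if v not in planted and rng.random() < config.sampling_fraction}
            layer_nodes[(t, cond)] = set(planted) | extra
        # Venn exactness: evict accidental all-layer commons from one layer.
        keys = [(t, cond) for t in tissues]
        accidental = set.intersection(*(layer_nodes[k] for k in keys)) - planted
        for v in sorted(accidental):
            k = keys[int(rng.integers(len(keys)))]
            layer_nodes[k].discard(v)

    g.graph["modules"] = modules
    family = LayerFamily()
    for (t, cond), nodes in layer_nodes.items():
        sub = nx.Graph(g.subgraph(nodes))
        sub.graph.pop("modules", None)
        family.add(t, cond, InteractionNetwork(sub, name=f"{t}_{cond}"))

    truth = GroundTruth(
        common_disease=common_d,
        common_normal=common_n,
        bridge_edges=bridge_edges,
        connectors=connectors,
        connector_anchors=connector_anchors,
        duplicate_pairs=duplicate_pairs,
        layer_nodes=layer_nodes,
        master=InteractionNetwork(g, name="synthetic_master"),
    )
    return family, truth


def sample_piecewise_powerlaw(
    n: int,
    exponent_low: float = 1.2,
    exponent_high: float = 3.0,
    k_break: int = 20,
    k_min: int = 1,
    k_max: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Sample integer degrees from an exact two-regime power law.

    P(k) is proportional to k**-exponent_low for k_min <= k <= k_break and
    to C * k**-exponent_high above, with C chosen for continuity at the
    break.  Used to validate the two-power-law fitter against a known law.
    """
    k = np.arange(k_min, k_max + 1, dtype=float)
    p = np.where(
        k <= k_break,
        k ** -exponent_low,
        k_break ** (exponent_high - exponent_low) * k ** -exponent_high,
    )
    p /= p.sum()
    rng = np.random.default_rng(seed)
    return rng.choice(np.arange(k_min, k_max + 1), size=n, p=p)


def write_family(
    family: LayerFamily, truth: GroundTruth, interactome: InteractionNetwork,
    out_dir: str | Path,
) -> None:
    """Write interactome TSV, per-layer protein lists, manifest YAML and
    ground_truth.json into a directory (the `synth` CLI output)."""
    import yaml

    from .graph_io import write_network

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_network(interactome, out / "interactome.tsv", format="tsv")
    manifest = {"interactome": "interactome.tsv", "layers": []}
    for (t, cond), net in sorted(family.items()):
        fname = f"{t}_{cond}.proteins.txt"
        (out / fname).write_text("\n".join(sorted(map(str, net.nodes))) + "\n")
        manifest["layers"].append({"tissue": t, "condition": cond, "proteins": fname})
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    truth.to_json(out / "ground_truth.json")
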