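"""ER and configuration-model null ensembles matched to a reference network.

The Erdos-Renyi match preserves N and the mean degree through the linking
probability p = <k>/N (the conventional small bias of /N rather than
/(N-1) is kept deliberately).  The configuration match additionally
preserves the degree sequence by uniform stub pairing; self-loops and
multi-edges produced by the pairing are either erased afterwards (default,
scales to interactome sizes; the degree-sequence deviation is logged) or
avoided by resampling until a simple graph appears (exact, small graphs).

Any metric from the structural/spectral/weak-ties suites can be summarized
over an ensemble of realizations (default 20) with full seeded determinism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import spectral, structural, weak_ties
from .graph_io import InteractionNetwork

logger = logging.getLogger(__name__)

DEFAULT_REALIZATIONS = 20


def generate_er(n: int, mean_degree: float, seed: int) -> InteractionNetwork:
    """One ER realization: each pair linked independently with p = <k>/N."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= mean_degree <= n - 1:
        raise ValueError(f"mean_degree must be in [0, N-1], got {mean_degree}")
    p = mean_degree / n
    g = nx.gnp_random_graph(n, p, seed=seed)
    return InteractionNetwork(g, name=f"ER(n={n},k={mean_degree:g})")


def generate_configuration(
    degree_sequence: Sequence[int],
    seed: int,
    scheme: str = "erase",
    max_attempts: int = 500,
) -> InteractionNetwork:
    """One configuration-model realization for a degree sequence.

    ``scheme='erase'`` collapses multi-edges and drops self-loops after the
    stub pairing (approximate degree preservation; deviation logged);
    ``scheme='rejection'`` resamples the pairing until it is simple (exact;
    errors after ``max_attempts`` suggesting the erase scheme).
    """
    degs = [int(d) for d in degree_sequence]
    if sum(degs) % 2 != 0:
        raise ValueError("degree sequence must have an even sum")
    if degs and max(degs) >= len(degs):
        raise ValueError("max degree must be < N for a simple realization")
    rng = np.random.default_rng(seed)
    if scheme == "erase":
        multi = nx.configuration_model(degs, seed=int(rng.integers(2**31)))
        g = nx.Graph(multi)
        g.remove_edges_from(nx.selfloop_edges(g))
        target_edges = sum(degs) // 2
        lost = target_edges - g.number_of_edges()
        if lost:
            logger.info(
                "configuration(erase): %d/%d edge(s) lost to self-loops/multi-edges",
                lost, target_edges,
            )
        return InteractionNetwork(g, name="configuration")
    if scheme == "rejection":
        for _ in range(max_attempts):
            multi = nx.configuration_model(degs, seed=int(rng.integers(2**31)))
            if nx.number_of_selfloops(multi) == 0 and max(
                (c for _u, _v, c in multi.edges(keys=True)), default=0
            ) == 0:
                return InteractionNetwork(nx.Graph(multi), name="configuration")
        raise RuntimeError(
            f"no simple pairing found in {max_attempts} attempts; "
            "use scheme='erase' for this degree sequence"
        )
    raise ValueError(f"unknown scheme {scheme!r} (expected 'erase' or 'rejection')")


# ---------------------------------------------------------------------------
# Metric registry
# ---------------------------------------------------------------------------

def _mean_degree(net):
    _n, _m, k, _d = structural.degree_statistics(net)
    return k


def _mean_clustering(net):
    return structural.clustering_coefficients(net)[1]


def _diameter(net):
    return float(structural.network_diameter(net)[0])


METRICS: dict[str, Callable[[InteractionNetwork], float]] = {
    "n_edges": lambda net: float(net.n_edges),
    "mean_degree": _mean_degree,
    "mean_clustering": _mean_clustering,
    "diameter": _diameter,
    "assortativity": structural.assortativity,
    "count_zero": lambda net: float(spectral.count_degeneracy(net, 0)),
    "count_minus_one": lambda net: float(spectral.count_degeneracy(net, -1)),
    "overlap_betweenness_correlation": weak_ties.overlap_betweenness_correlation,
}


@dataclass
class EnsembleSummary:
    """Per-metric mean/sd and per-realization values over a null ensemble."""

    model: str
    n_realizations: int
    seed: int
    values: pd.DataFrame  # one row per realization, one column per metric
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.mean = {c: float(np.nanmean(self.values[c])) for c in self.values.columns}
        self.sd = {c: float(np.nanstd(self.values[c], ddof=1)) for c in self.values.columns}


def ensemble_summary(
    reference_net: InteractionNetwork,
    model: str,
    metrics: Iterable[str],
    n_realizations: int = DEFAULT_REALIZATIONS,
    seed: int = 0,
    scheme: str = "erase",
) -> EnsembleSummary:
    """Evaluate metrics over an ensemble of null networks matched to a reference.

    ``model`` is ``'ER'`` (match N and <k>) or ``'configuration'`` (match the
    degree sequence).  Deterministic under a fixed seed: realization i uses
    child seed derived from (seed, i).
    """
    metrics = list(metrics)
    for m in metrics:
        if m not in METRICS:
            raise ValueError(f"unknown metric {m!r}; available: {sorted(METRICS)}")
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    n = reference_net.n_nodes
    mean_k = 2.0 * reference_net.n_edges / n if n else 0.0
    degs = [d for _v, d in reference_net.graph.degree()]
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_realizations)]
    rows = []
    for i, child in enumerate(child_seeds):
        if model.upper() == "ER":
            net = generate_er(n, mean_k, seed=child)
        elif model.lower() in ("configuration", "config"):
            net = generate_configuration(degs, seed=child, scheme=scheme)
        else:
            raise ValueError(f"unknown model {model!r} (expected 'ER' or 'configuration')")
        row = {}
        for m in metrics:
            try:
                row[m] = float(METRICS[m](net))
            except ValueError:
                row[m] = float("nan")
        rows.append(row)
    values = pd.DataFrame(rows, columns=metrics)
    values.insert(0, "realization", range(n_realizations))
    values = values.set_index("realization")
    return EnsembleSummary(model=model, n_realizations=n_realizations, seed=seed, values=values)
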