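"""Per-network structural metrics for PPI-style graphs.

Covers the standard suite used to profile interactomes: degree statistics,
clustering, diameter (on the largest connected component), degree
assortativity from the edge-sum formula, unnormalized betweenness
centrality, degree-metric Pearson correlations, and a two-regime power-law
fit of the degree distribution.

Conventions, stated once:

* betweenness is the Brandes sum over *unordered* source-target pairs,
  endpoints excluded, unnormalized;
* clustering of degree-0/1 nodes is 0 and included in the average (a flag
  excludes them);
* undefined correlations (zero variance) are reported as NaN, never 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .graph_io import InteractionNetwork


@dataclass
class StructuralSummary:
    """One network's structural metric bundle (one row of a summary table)."""

    name: str
    n_nodes: int
    n_edges: int
    mean_degree: float
    mean_clustering: float
    diameter: int
    lcc_fraction: float
    assortativity: float
    corr_k_cc: float
    corr_k_betweenness: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TwoPowerLawFit:
    """Piecewise (two-segment) power-law fit of a degree distribution.

    ``exponent_low``/``exponent_high`` are the positive exponents gamma of
    P(k) ~ k**(-gamma) below and above ``breakpoint_degree``; ``sse`` is the
    total squared residual of the two log-log least-squares lines.
    """

    breakpoint_degree: float
    exponent_low: float
    exponent_high: float
    sse: float
    n_bins_low: int
    n_bins_high: int


def _graph(net: InteractionNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, InteractionNetwork) else net


def degree_statistics(net) -> tuple[int, int, float, list[int]]:
    """Return (N, N_C, mean degree, degree sequence).  <k> = 2 N_C / N."""
    g = _graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("degree statistics undefined for an empty network")
    degrees = [d for _n, d in g.degree()]
    n, m = g.number_of_nodes(), g.number_of_edges()
    return n, m, 2.0 * m / n, degrees


def clustering_coefficients(
    net, include_low_degree: bool = True
) -> tuple[dict, float]:
    """Per-node clustering CC_i = 2 t_i / (k_i (k_i - 1)) and its average.

    CC_i is 0 for nodes of degree < 2; those nodes are included in the
    average unless ``include_low_degree`` is False (the denominator of the
    average is a convention, so both are exposed).
    """
    g = _graph(net)
    cc = nx.clustering(g)
    if not cc:
        return {}, float("nan")
    if include_low_degree:
        mean = float(np.mean(list(cc.values())))
    else:
        vals = [c for n, c in cc.items() if g.degree(n) >= 2]
        mean = float(np.mean(vals)) if vals else float("nan")
    return cc, mean


def network_diameter(net) -> tuple[int, float]:
    """Diameter of the largest connected component and the LCC node fraction.

    Ties between equal-sized components are broken toward the component
    containing the lexicographically smallest node, so the result is
    deterministic on disconnected graphs.
    """
    g = _graph(net)
    if g.number_of_edges() == 0:
        raise ValueError("diameter undefined: network has no edges")
    comps = list(nx.connected_components(g))
    lcc = min(comps, key=lambda c: (-len(c), min(str(n) for n in c)))
    d = nx.diameter(g.subgraph(lcc))
    return int(d), len(lcc) / g.number_of_nodes()


def assortativity(net) -> float:
    """Degree-degree correlation r from the edge-sum (Newman) formula.

    With (j_i, k_i) the endpoint degrees of edge i and M the edge count
    (each undirected edge counted once, endpoint order symmetrized by the
    half-sums)::

        r = [M^-1 sum j k - (M^-1 sum (j+k)/2)^2]
            / [M^-1 sum (j^2+k^2)/2 - (M^-1 sum (j+k)/2)^2]

    Returns NaN when the denominator vanishes (e.g. any regular graph).
    """
    g = _graph(net)
    m = g.number_of_edges()
    if m < 2:
        raise ValueError("assortativity requires at least 2 edges")
    deg = dict(g.degree())
    j = np.array([deg[u] for u, _v in g.edges()], dtype=float)
    k = np.array([deg[v] for _u, v in g.edges()], dtype=float)
    num = np.mean(j * k) - np.mean((j + k) / 2.0) ** 2
    den = np.mean((j**2 + k**2) / 2.0) - np.mean((j + k) / 2.0) ** 2
    if math.isclose(den, 0.0, abs_tol=1e-12):
        return float("nan")
    return float(num / den)


def betweenness_centrality(net) -> dict:
    """Unnormalized node betweenness beta_c over unordered pairs.

    beta_c(i) = sum over pairs {s,t}, s != t != i, of g_st(i)/g_st, where
    g_st counts shortest s-t paths; disconnected pairs contribute 0.
    """
    g = _graph(net)
    return nx.betweenness_centrality(g, normalized=False)


def metric_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation of two per-node (or per-edge) metric vectors.

    NaN entries are dropped pairwise.  Returns NaN if either variance is
    zero.  Raises on length mismatch or fewer than 3 usable pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 (non-missing) value pairs")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def structural_summary(net, name: str | None = None) -> StructuralSummary:
    """Compute the full structural bundle for one network."""
    g = _graph(net)
    label = name if name is not None else getattr(net, "name", "")
    n, m, mean_k, degrees = degree_statistics(net)
    cc, mean_cc = clustering_coefficients(net)
    d, lcc_frac = network_diameter(net) if m > 0 else (0, 0.0)
    r = assortativity(net) if m >= 2 else float("nan")
    bc = betweenness_centrality(net)
    nodes = list(g.nodes)
    k_vec = [g.degree(v) for v in nodes]
    try:
        corr_k_cc = metric_correlation(k_vec, [cc[v] for v in nodes])
    except ValueError:
        corr_k_cc = float("nan")
    try:
        corr_k_bc = metric_correlation(k_vec, [bc[v] for v in nodes])
    except ValueError:
        corr_k_bc = float("nan")
    return StructuralSummary(
        name=label, n_nodes=n, n_edges=m, mean_degree=mean_k,
        mean_clustering=mean_cc, diameter=d, lcc_fraction=lcc_frac,
        assortativity=r, corr_k_cc=corr_k_cc, corr_k_betweenness=corr_k_bc,
    )


# ---------------------------------------------------------------------------
# Two-regime power-law fit
# ---------------------------------------------------------------------------

def log_binned_pk(
    degrees: Iterable[int], bins_per_decade: int = 6, min_count: int = 5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Logarithmically binned degree density P(k) for integer degrees.

    Bin edges are log-spaced but snapped to integers, so every bin covers
    whole degrees and no bin is narrower than 1 (fractional-width bins at
    small k would otherwise inflate the density there).  Returns
    (geometric bin centers, density, occupancy counts) over bins holding at
    least ``min_count`` observations — sparser bins carry almost no
    information about log P(k).  A power law P(k) ~ k^-gamma appears as a
    line of slope -gamma in log-log space.  Degree-0 nodes are excluded.
    """
    degrees = np.asarray([d for d in degrees if d > 0], dtype=float)
    if degrees.size == 0:
        raise ValueError("no positive degrees")
    lo, hi = degrees.min(), degrees.max()
    n_decades = max(np.log10(hi / lo), 1e-9)
    n_bins = max(int(np.ceil(n_decades * bins_per_decade)), 2)
    raw = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    edges = sorted({int(np.floor(e)) for e in raw})
    if edges[-1] <= hi:
        edges.append(int(hi) + 1)
    edges = np.asarray(edges, dtype=float)
    counts, _ = np.histogram(degrees, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * np.maximum(edges[1:] - 1, edges[:-1]))
    dens = counts / (degrees.size * widths)
    keep = counts >= min_count
    return centers[keep], dens[keep], counts[keep]


def _wlsq_line(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float, float]:
    """Count-weighted least-squares line; returns (slope, intercept, weighted SSE).

    Weighting by bin occupancy reflects the ~1/count variance of a log
    density estimate, so sparse tail bins cannot dominate the fit.
    """
    sw = np.sqrt(w)
    a = np.vstack([x, np.ones_like(x)]).T
    coef, *_ = np.linalg.lstsq(a * sw[:, None], y * sw, rcond=None)
    res = y - a @ coef
    return float(coef[0]), float(coef[1]), float(np.sum(w * res**2))


def fit_two_powerlaws(
    degrees: Iterable[int],
    bins_per_decade: int = 6,
    min_bins_per_segment: int = 3,
    breakpoint_range: tuple[float, float] | None = None,
) -> TwoPowerLawFit:
    """Fit two power-law regimes to a degree distribution.

    The empirical log-binned P(k) is split at every candidate breakpoint
    (each interior bin boundary leaving >= ``min_bins_per_segment`` bins on
    each side, optionally restricted to ``breakpoint_range``); an
    occupancy-weighted least-squares line is fitted to log P(k) vs log k on
    each side, and the breakpoint minimizing the total weighted SSE wins
    (ties -> smaller breakpoint).  Continuity at the break is not enforced.
    """
    degrees = [int(d) for d in degrees]
    if len(set(d for d in degrees if d > 0)) < 20:
        raise ValueError("insufficient support: need >= 20 distinct positive degrees")
    centers, dens, counts = log_binned_pk(degrees, bins_per_decade=bins_per_decade)
    lx, ly, w = np.log10(centers), np.log10(dens), counts.astype(float)
    best: TwoPowerLawFit | None = None
    for i in range(min_bins_per_segment, len(centers) - min_bins_per_segment + 1):
        bp = math.sqrt(centers[i - 1] * centers[i])  # between the two segments
        if breakpoint_range is not None and not (breakpoint_range[0] <= bp <= breakpoint_range[1]):
            continue
        s1, _b1, e1 = _wlsq_line(lx[:i], ly[:i], w[:i])
        s2, _b2, e2 = _wlsq_line(lx[i:], ly[i:], w[i:])
        sse = e1 + e2
        if best is None or sse < best.sse - 1e-15:
            best = TwoPowerLawFit(
                breakpoint_degree=bp, exponent_low=-s1, exponent_high=-s2,
                sse=sse, n_bins_low=i, n_bins_high=len(centers) - i,
            )
    if best is None:
        raise ValueError("insufficient support: too few log bins for two segments")
    return best


# ---------------------------------------------------------------------------
# Tidy output
# ---------------------------------------------------------------------------

def summaries_to_frame(summaries: Iterable[StructuralSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in summaries])


def write_summaries(
    summaries: Iterable[StructuralSummary], path: str | Path, format: str = "tsv"
) -> None:
    """Write summaries as tidy TSV (one row per network) or JSON."""
    path = Path(path)
    frame = summaries_to_frame(summaries)
    if format == "tsv":
        frame.to_csv(path, sep="\t", index=False)
    elif format == "json":
        path.write_text(json.dumps(frame.to_dict(orient="records"), indent=2))
    else:
        raise ValueError(f"unknown format {format!r}")
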