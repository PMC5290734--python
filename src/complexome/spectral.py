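"""Adjacency-spectrum analysis: eigenvalue degeneracies and duplicate nodes.

For a simple undirected graph with 0/1 adjacency matrix A, the multiplicity
of the eigenvalue 0 equals the rank deficiency of A and that of -1 equals
the rank deficiency of A + I.  Node duplication leaves an exact fingerprint
here: a class of c nodes sharing identical neighborhoods (rows of A)
contributes c - 1 zero eigenvalues, and a class of c *adjacent twins*
(identical rows of A + I, e.g. the vertices of a clique) contributes c - 1
eigenvalues at -1.  Degeneracy beyond those bounds is attributed to partial
duplication (rows equal to sums of other rows) and similar linear structure,
which is reported as inferred slack rather than enumerated.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .graph_io import InteractionNetwork

logger = logging.getLogger(__name__)

_DENSE_WARN_N = 5000


class DegeneracyMismatchError(RuntimeError):
    """Rank-deficiency and eigenvalue-bin degeneracy counts disagree."""


def _graph(net) -> nx.Graph:
    return net.graph if isinstance(net, InteractionNetwork) else net


def _adjacency(net) -> tuple[np.ndarray, list]:
    g = _graph(net)
    nodes = list(g.nodes)
    if len(nodes) > _DENSE_WARN_N:
        warnings.warn(
            f"dense eigensolve on N={len(nodes)} nodes may be slow", stacklevel=3
        )
    return nx.to_numpy_array(g, nodelist=nodes, dtype=float), nodes


@dataclass
class SpectralSummary:
    """Spectral metric bundle for one network."""

    name: str
    eigenvalues: np.ndarray
    count_zero: int
    count_minus_one: int
    duplicate_classes: list[frozenset] = field(default_factory=list)
    adjacent_twin_classes: list[frozenset] = field(default_factory=list)
    bound_zero: int = 0
    bound_minus_one: int = 0

    @property
    def inferred_partial_duplication(self) -> int:
        """Zero-eigenvalue degeneracy not explained by complete duplicates."""
        return self.count_zero - self.bound_zero


def adjacency_spectrum(net) -> np.ndarray:
    """Full real spectrum of the symmetric adjacency matrix, descending."""
    a, _nodes = _adjacency(net)
    if a.shape[0] == 0:
        raise ValueError("spectrum undefined for an empty network")
    return np.sort(np.linalg.eigvalsh(a))[::-1]


def count_degeneracy(net, target: int, eigenvalues: np.ndarray | None = None) -> int:
    """Multiplicity of ``target`` (0 or -1) in the adjacency spectrum.

    Counted as integer rank deficiency (N - rank of A, resp. A + I), which
    is exact for integer matrices; cross-checked against tolerance-binned
    eigenvalue counting, raising :class:`DegeneracyMismatchError` on
    disagreement so numerical pathology surfaces instead of hiding.
    """
    if target not in (0, -1):
        raise ValueError("target eigenvalue must be 0 or -1")
    a, _nodes = _adjacency(net)
    n = a.shape[0]
    mat = a if target == 0 else a + np.eye(n)
    rank = int(np.linalg.matrix_rank(mat))  # SVD with N*eps*sigma_max threshold
    by_rank = n - rank
    if eigenvalues is None:
        eigenvalues = np.linalg.eigvalsh(a)
    smax = float(np.max(np.abs(eigenvalues))) if n else 0.0
    tol = 1e-8 * max(1.0, smax)
    by_eig = int(np.sum(np.abs(eigenvalues - target) < tol))
    if by_rank != by_eig:
        raise DegeneracyMismatchError(
            f"degeneracy at {target}: rank-based {by_rank} != eigenvalue-based {by_eig}"
        )
    return by_rank


def find_duplicate_nodes(net) -> tuple[list[frozenset], list[frozenset]]:
    """Classes of complete-duplicate and adjacent-twin nodes.

    * ``duplicate_classes``: nodes with identical neighbor sets (identical
      rows of A; such nodes are necessarily non-adjacent).
    * ``adjacent_twin_classes``: nodes with identical closed neighborhoods
      (identical rows of A + I, e.g. clique members with the same outside
      neighbors).

    Detection hashes canonical neighbor sets, O(N + E) expected; classes of
    size 1 are omitted.
    """
    g = _graph(net)
    open_nbrs: dict[frozenset, set] = {}
    closed_nbrs: dict[frozenset, set] = {}
    for v in g.nodes:
        nbrs = frozenset(g.neighbors(v))
        open_nbrs.setdefault(nbrs, set()).add(v)
        closed_nbrs.setdefault(nbrs | {v}, set()).add(v)
    dup = [frozenset(c) for c in open_nbrs.values() if len(c) >= 2]
    twin = [frozenset(c) for c in closed_nbrs.values() if len(c) >= 2]
    key = lambda c: sorted(str(v) for v in c)
    return sorted(dup, key=key), sorted(twin, key=key)


def duplication_lower_bounds(
    duplicate_classes: list[frozenset], adjacent_twin_classes: list[frozenset]
) -> tuple[int, int]:
    """Lower bounds on the 0 and -1 degeneracies implied by duplication.

    Each class of size c contributes c - 1 linearly dependent rows, hence
    c - 1 eigenvalues at the corresponding value.
    """
    bound_zero = sum(len(c) - 1 for c in duplicate_classes)
    bound_minus_one = sum(len(c) - 1 for c in adjacent_twin_classes)
    return bound_zero, bound_minus_one


def spectral_summary(net, name: str | None = None) -> SpectralSummary:
    """Full spectral bundle; verifies the duplication lower bounds hold."""
    label = name if name is not None else getattr(net, "name", "")
    eig = adjacency_spectrum(net)
    c0 = count_degeneracy(net, 0, eigenvalues=eig)
    c1 = count_degeneracy(net, -1, eigenvalues=eig)
    dup, twin = find_duplicate_nodes(net)
    b0, b1 = duplication_lower_bounds(dup, twin)
    if c0 < b0 or c1 < b1:
        raise RuntimeError(
            f"duplication bound violated (count_zero={c0} < {b0} or "
            f"count_minus_one={c1} < {b1}): implementation bug"
        )
    return SpectralSummary(
        name=label, eigenvalues=eig, count_zero=c0, count_minus_one=c1,
        duplicate_classes=dup, adjacent_twin_classes=twin,
        bound_zero=b0, bound_minus_one=b1,
    )


def duplicate_node_set(net) -> set:
    """All nodes participating in any duplicate or adjacent-twin class."""
    dup, twin = find_duplicate_nodes(net)
    out: set = set()
    for c in dup + twin:
        out |= set(c)
    return out


def compare_duplicates(net_a, net_b) -> dict:
    """Compare the duplicate-node sets of two networks (e.g. normal vs disease).

    Returns shared / exclusive node sets and their Jaccard index (defined
    as 1.0 when both sets are empty).
    """
    da, db = duplicate_node_set(net_a), duplicate_node_set(net_b)
    union = da | db
    jaccard = (len(da & db) / len(union)) if union else 1.0
    return {
        "shared": da & db,
        "only_a": da - db,
        "only_b": db - da,
        "jaccard": jaccard,
    }


def write_spectrum(eigenvalues: np.ndarray, path: str | Path) -> None:
    """One eigenvalue per line, descending."""
    Path(path).write_text("\n".join(f"{x:.12g}" for x in eigenvalues) + "\n")


def write_duplicate_classes(classes: list[frozenset], path: str | Path) -> None:
    """Duplicate classes as JSON {class_id: [node, ...]}."""
    payload = {str(i): sorted(str(v) for v in c) for i, c in enumerate(classes)}
    Path(path).write_text(json.dumps(payload, indent=2))
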