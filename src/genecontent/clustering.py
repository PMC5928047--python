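"""Homology-group inference: BLAST tabular parsing, similarity-graph
construction and Markov clustering (MCL).

The pipeline mirrors standard comparative-genomics practice: all-vs-all
protein BLAST hits are filtered at an e-value threshold, turned into a
weighted undirected graph (weight = capped −log10 e-value, reciprocal hits
combined), and partitioned into homology groups (HGs) by MCL — alternating
expansion (matrix power) and inflation (entrywise power + column
renormalisation) on the column-stochastic transition matrix until
convergence, then reading clusters off the attractor structure.

MCL is implemented here on scipy sparse matrices; it is deterministic
(nodes are processed in sorted order) and invariant to the input node order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from os import PathLike
from typing import Callable, Iterable, Iterator, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .errors import BlastFormatError, ClusterFormatError, InputError
from .io import resolve_species_of

__all__ = [
    "GraphBuildParams",
    "MCLParams",
    "MCLStats",
    "HomologyGroupSet",
    "parse_blast_tab",
    "evalue_to_weight",
    "weight_to_evalue",
    "build_similarity_graph",
    "mcl_cluster",
    "mcl_cluster_with_stats",
    "read_clusters",
    "write_clusters",
]


# --------------------------------------------------------------------- params


@dataclass(frozen=True)
class GraphBuildParams:
    """How BLAST hits become edge weights.

    evalue_max      hits above this e-value are discarded (default 1e-5)
    weight_cap      weight assigned to e-value 0 and ceiling for all weights
    symmetrization  rule combining reciprocal hits: "max" (default), "min",
                    or "mean"
    """

    evalue_max: float = 1e-5
    weight_cap: float = 200.0
    symmetrization: str = "max"

    def __post_init__(self):
        if not self.evalue_max > 0:
            raise InputError("evalue_max must be > 0")
        if not self.weight_cap > 0:
            raise InputError("weight_cap must be > 0")
        if self.symmetrization not in ("max", "min", "mean"):
            raise InputError(f"unknown symmetrization {self.symmetrization!r}")


@dataclass(frozen=True)
class MCLParams:
    """Markov-clustering controls.

    inflation        granularity exponent (> 1; default 2.0, the MCL default)
    expansion        matrix-power exponent per iteration (integer >= 2)
    prune_threshold  entries below this are dropped after each inflation
    tol              convergence: max entrywise change between iterates
    max_iterations   hard cap; non-convergence emits a warning
    """

    inflation: float = 2.0
    expansion: int = 2
    prune_threshold: float = 1e-5
    tol: float = 1e-6
    max_iterations: int = 100

    def __post_init__(self):
        if not self.inflation > 1:
            raise InputError("inflation must be > 1")
        if int(self.expansion) != self.expansion or self.expansion < 2:
            raise InputError("expansion must be an integer >= 2")
        if not self.tol > 0:
            raise InputError("tol must be > 0")
        if not self.prune_threshold >= 0:
            raise InputError("prune_threshold must be >= 0")


@dataclass
class MCLStats:
    """Diagnostics from an MCL run."""

    iterations: int = 0
    converged: bool = False
    final_change: float = math.inf
    max_colsum_deviation: float = 0.0  # worst |column sum - 1| after inflation


# -------------------------------------------------------------------- parsing


def _iter_lines(source) -> Iterator[str]:
    if isinstance(source, (str, PathLike)):
        with open(source) as fh:
            yield from fh
    else:
        yield from source


def parse_blast_tab(
    source, evalue_max: float = 1e-5
) -> list[tuple[str, str, float]]:
    """Parse 12-column BLAST ``-outfmt 6`` lines into (query, subject, evalue)
    hits, keeping hits with evalue <= evalue_max and dropping self-hits.

    ``source`` may be a path or any iterable of lines. Malformed lines raise
    :class:`BlastFormatError` naming the line number.
    """
    hits: list[tuple[str, str, float]] = []
    for lineno, raw in enumerate(_iter_lines(source), 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 12:
            raise BlastFormatError(
                f"line {lineno}: expected 12 tab-separated columns, got {len(parts)}"
            )
        q, s = parts[0], parts[1]
        try:
            evalue = float(parts[10])
        except ValueError:
            raise BlastFormatError(
                f"line {lineno}: non-numeric e-value {parts[10]!r}"
            ) from None
        if evalue < 0:
            raise BlastFormatError(f"line {lineno}: negative e-value {evalue}")
        if q == s:
            continue
        if evalue <= evalue_max:
            hits.append((q, s, evalue))
    return hits


# ------------------------------------------------------------- graph building


def evalue_to_weight(evalue: float, cap: float = 200.0) -> float:
    """w = min(−log10 e, cap); an e-value of exactly 0 gets the cap."""
    if evalue <= 0:
        return cap
    return min(-math.log10(evalue), cap)


def weight_to_evalue(weight: float, cap: float = 200.0) -> float:
    """Inverse of :func:`evalue_to_weight`; weights at/above the cap map to 0
    (the transform is not invertible there)."""
    if weight >= cap:
        return 0.0
    return 10.0 ** (-weight)


def build_similarity_graph(
    hits: Iterable[tuple[str, str, float]],
    params: GraphBuildParams | None = None,
    protein_ids: Iterable[str] | None = None,
) -> nx.Graph:
    """Weighted undirected similarity graph from filtered BLAST hits.

    Reciprocal/duplicate hits are combined according to
    ``params.symmetrization``. Proteins listed in ``protein_ids`` but hit-less
    become isolated nodes (they will cluster as singletons).
    """
    params = params or GraphBuildParams()
    acc: dict[tuple[str, str], list[float]] = {}
    for q, s, evalue in hits:
        if q == s:
            continue
        key = (q, s) if q <= s else (s, q)
        acc.setdefault(key, []).append(evalue_to_weight(evalue, params.weight_cap))

    combine = {"max": max, "min": min, "mean": lambda ws: sum(ws) / len(ws)}[
        params.symmetrization
    ]
    graph = nx.Graph()
    if protein_ids is not None:
        graph.add_nodes_from(protein_ids)
    for (u, v), weights in acc.items():
        graph.add_edge(u, v, weight=float(combine(weights)))
    return graph


# ------------------------------------------------------------ homology groups


class HomologyGroupSet:
    """A partition of proteins into homology groups.

    Each HG has a stable ID (``HG000001``, ...) and an ordered member tuple.
    Every protein belongs to exactly one HG; singletons count as HGs.
    """

    def __init__(self, clusters: Iterable[Iterable[str]]):
        self._clusters: list[tuple[str, ...]] = [tuple(c) for c in clusters]
        seen: dict[str, int] = {}
        for ci, members in enumerate(self._clusters):
            if not members:
                raise ClusterFormatError("empty cluster")
            for pid in members:
                if pid in seen:
                    raise ClusterFormatError(
                        f"protein {pid!r} appears in more than one cluster"
                    )
                seen[pid] = ci
        self._ids = [f"HG{i + 1:06d}" for i in range(len(self._clusters))]
        self._member_index = seen

    # container protocol -----------------------------------------------------

    def __len__(self) -> int:
        return len(self._clusters)

    def __iter__(self) -> Iterator[tuple[str, tuple[str, ...]]]:
        return iter(zip(self._ids, self._clusters))

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self._ids)

    @property
    def clusters(self) -> tuple[tuple[str, ...], ...]:
        return tuple(self._clusters)

    @property
    def n_proteins(self) -> int:
        return len(self._member_index)

    def members(self, hg_id: str) -> tuple[str, ...]:
        try:
            return self._clusters[self._ids.index(hg_id)]
        except ValueError:
            raise InputError(f"unknown HG ID {hg_id!r}") from None

    def hg_of(self, protein_id: str) -> str:
        try:
            return self._ids[self._member_index[protein_id]]
        except KeyError:
            raise InputError(f"protein {protein_id!r} not in any HG") from None

    # conversions ------------------------------------------------------------

    def to_occupancy(
        self, species_of: Mapping[str, str] | Callable[[str], str]
    ) -> pd.DataFrame:
        """HG × species gene-count table (presence = count >= 1)."""
        extract = resolve_species_of(species_of)
        species = sorted({extract(p) for p in self._member_index})
        col = {s: j for j, s in enumerate(species)}
        counts = np.zeros((len(self._clusters), len(species)), dtype=np.int64)
        for i, members in enumerate(self._clusters):
            for pid in members:
                counts[i, col[extract(pid)]] += 1
        df = pd.DataFrame(counts, index=pd.Index(self._ids, name="hg"), columns=species)
        return df


def write_clusters(hgset: HomologyGroupSet, path_or_handle) -> None:
    """MCL dump dialect: one cluster per line, tab-separated member IDs."""
    if isinstance(path_or_handle, (str, PathLike)):
        with open(path_or_handle, "w") as fh:
            write_clusters(hgset, fh)
        return
    for _, members in hgset:
        path_or_handle.write("\t".join(members) + "\n")


def read_clusters(source) -> HomologyGroupSet:
    """Inverse of :func:`write_clusters`; duplicate proteins across lines are
    a format error naming the protein."""
    clusters = []
    for raw in _iter_lines(source):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        clusters.append(line.split("\t"))
    return HomologyGroupSet(clusters)


# ------------------------------------------------------------------------ MCL


def _column_normalize(M: sparse.csc_matrix) -> sparse.csc_matrix:
    sums = np.asarray(M.sum(axis=0)).ravel()
    empty = np.flatnonzero(sums == 0)
    if empty.size:
        # a column pruned to nothing keeps its node as its own attractor
        fix = sparse.csc_matrix(
            (np.ones(empty.size), (empty, empty)), shape=M.shape
        )
        M = (M + fix).tocsc()
        sums = np.asarray(M.sum(axis=0)).ravel()
    inv = sparse.diags(1.0 / sums)
    return (M @ inv).tocsc()


def mcl_cluster_with_stats(
    graph: nx.Graph, params: MCLParams | None = None
) -> tuple[HomologyGroupSet, MCLStats]:
    """Run MCL on a weighted undirected graph, returning the homology-group
    partition and convergence diagnostics.

    Each node receives a self-loop weighted at its maximum incident edge
    weight (1.0 for isolated nodes) before column normalisation — the
    standard MCL regularisation. Clusters are the connected components of the
    converged matrix's support (entries >= prune_threshold); isolated nodes
    come out as singleton HGs. Output is independent of node insertion order.
    """
    params = params or MCLParams()
    stats = MCLStats()
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        stats.converged = True
        return HomologyGroupSet([]), stats
    index = {u: i for i, u in enumerate(nodes)}

    rows, cols, vals = [], [], []
    loop = np.zeros(n)
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w < 0:
            raise InputError(f"negative edge weight on ({u!r}, {v!r})")
        if u == v:
            continue  # self-loops are regenerated internally
        i, j = index[u], index[v]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
        loop[i] = max(loop[i], w)
        loop[j] = max(loop[j], w)
    loop[loop == 0] = 1.0
    rows += list(range(n))
    cols += list(range(n))
    vals += list(loop)

    M = sparse.csc_matrix((vals, (rows, cols)), shape=(n, n))
    M = _column_normalize(M)

    for it in range(1, params.max_iterations + 1):
        stats.iterations = it
        New = M
        for _ in range(params.expansion - 1):
            New = (New @ M).tocsc()
        New = New.power(params.inflation)
        New = _column_normalize(New)
        dev = float(np.abs(np.asarray(New.sum(axis=0)).ravel() - 1.0).max())
        stats.max_colsum_deviation = max(stats.max_colsum_deviation, dev)
        if params.prune_threshold > 0:
            New.data[New.data < params.prune_threshold] = 0.0
            New.eliminate_zeros()
            New = _column_normalize(New)
            dev = float(np.abs(np.asarray(New.sum(axis=0)).ravel() - 1.0).max())
            stats.max_colsum_deviation = max(stats.max_colsum_deviation, dev)
        diff = New - M
        stats.final_change = float(np.abs(diff.data).max()) if diff.nnz else 0.0
        M = New
        if stats.final_change < params.tol:
            stats.converged = True
            break
    if not stats.converged:
        warnings.warn(
            f"MCL did not converge in {params.max_iterations} iterations "
            f"(last change {stats.final_change:.2e}); clustering the last iterate",
            RuntimeWarning,
            stacklevel=2,
        )

    support = M.copy()
    if params.prune_threshold > 0:
        support.data[support.data < params.prune_threshold] = 0.0
        support.eliminate_zeros()
    support = ((support + support.T) > 0).astype(np.int8)
    n_comp, labels = connected_components(support, directed=False)
    groups: dict[int, list[str]] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(nodes[i])
    clusters = sorted(
        (sorted(members) for members in groups.values()),
        key=lambda c: (-len(c), c[0]),
    )
    return HomologyGroupSet(clusters), stats


def mcl_cluster(graph: nx.Graph, params: MCLParams | None = None) -> HomologyGroupSet:
    """Convenience wrapper around :func:`mcl_cluster_with_stats`."""
    hgset, _ = mcl_cluster_with_stats(graph, params)
    return hgset
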