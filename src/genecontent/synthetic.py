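"""Synthetic data with known ground truth.

Two generators back the test surface of the pipeline:

* a gene birth–death process on a species tree — homology groups (HGs) are
  born once on a branch (Poisson per branch, branch lengths ignored) and
  thereafter lost independently on each descendant branch with a fixed
  probability; losses remove the HG from the whole subtree below the branch.
  This produces an occupancy matrix together with the exact gain/loss
  history, the ground truth for classification tests. A separate step
  superimposes per-genome gene missingness, emulating incomplete assemblies
  and annotations.

* a planted-partition similarity graph — known cluster labels, dense within
  clusters and sparse between, with weights drawn from separate ranges —
  the ground truth for Markov-clustering recovery tests, writable as
  synthetic BLAST tabular output for parser round-trips.

Everything is a pure function of (inputs, seed): the same seed yields
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from os import PathLike
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .clustering import weight_to_evalue
from .errors import InputError
from .trees import SpeciesTree

__all__ = [
    "BirthDeathParams",
    "SimulatedTruth",
    "PlantedGraphParams",
    "simulate_hg_histories",
    "apply_incompleteness",
    "generate_planted_graph",
    "write_synthetic_blast",
]


# ---------------------------------------------------------------- birth–death


@dataclass(frozen=True)
class BirthDeathParams:
    """Gene birth–death controls.

    origins_per_branch  expected HG originations per branch (Poisson mean);
                        every node, including the root (its stem), hosts one
                        "branch"
    loss_prob           per-branch probability that an HG present at the
                        parent is lost on that branch (whole-subtree loss)
    seed                RNG seed; same seed + tree + params ⇒ identical output
    """

    origins_per_branch: float = 5.0
    loss_prob: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not self.origins_per_branch >= 0:
            raise InputError("origins_per_branch must be >= 0")
        if not 0.0 <= self.loss_prob <= 1.0:
            raise InputError("loss_prob must be in [0, 1]")


@dataclass
class SimulatedTruth:
    """Exact history of each simulated HG.

    origin      HG ID → node label where the HG was born
    losses      HG ID → labels of nodes whose parent-edge carried a loss
    possessors  HG ID → final possessor species (may be empty if every
                lineage lost the HG)
    """

    origin: dict[str, str] = field(default_factory=dict)
    losses: dict[str, frozenset[str]] = field(default_factory=dict)
    possessors: dict[str, frozenset[str]] = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("hg\torigin\tlosses\n")
            for hg in self.origin:
                losses = ";".join(sorted(self.losses[hg]))
                fh.write(f"{hg}\t{self.origin[hg]}\t{losses}\n")

    @classmethod
    def read(cls, path, tree: SpeciesTree) -> "SimulatedTruth":
        truth = cls()
        with open(path) as fh:
            header = fh.readline()
            if header.rstrip("\n").split("\t") != ["hg", "origin", "losses"]:
                raise InputError("bad truth-table header")
            for raw in fh:
                line = raw.rstrip("\n")
                if not line:
                    continue
                hg, origin, losses = line.split("\t")
                loss_set = frozenset(losses.split(";")) if losses else frozenset()
                truth.origin[hg] = origin
                truth.losses[hg] = loss_set
                truth.possessors[hg] = _possessors(tree, origin, loss_set)
        return truth


def _possessors(tree: SpeciesTree, origin: str, losses: frozenset[str]) -> frozenset[str]:
    mask = tree.leaf_mask(origin).copy()
    for node in losses:
        mask &= ~tree.leaf_mask(node)
    return frozenset(np.array(tree.leaf_names)[mask])


def simulate_hg_histories(
    tree: SpeciesTree, params: BirthDeathParams
) -> tuple[pd.DataFrame, SimulatedTruth]:
    """Simulate single-origin / multiple-loss HG histories on a tree.

    Each node's branch receives Poisson(origins_per_branch) new HGs; an HG
    born on the branch above node *o* is present at *o* and propagates to
    descendants, except below branches on which a loss fires
    (prob ``loss_prob`` per branch, evaluated only where the lineage still
    carries the HG). Occupancy counts are 1 for possessors, 0 otherwise —
    copy-number expansion is not simulated. HGs whose every lineage lost
    them remain as all-zero rows, aligned with the truth table.
    """
    if not isinstance(tree, SpeciesTree):
        raise InputError("tree must be a rooted SpeciesTree with >= 2 leaves")
    rng = np.random.default_rng(params.seed)
    truth = SimulatedTruth()
    rows: list[np.ndarray] = []
    hg_ids: list[str] = []
    counter = 0

    for origin in tree.preorder():
        n_new = int(rng.poisson(params.origins_per_branch))
        for _ in range(n_new):
            counter += 1
            hg = f"HG{counter:06d}"
            losses: set[str] = set()
            mask = np.zeros(tree.n_leaves, dtype=bool)
            stack = [origin]
            while stack:
                node = stack.pop()
                if tree.is_leaf(node):
                    mask[tree.leaf_column(node)] = True
                    continue
                for child in tree.children(node):
                    if params.loss_prob > 0 and rng.random() < params.loss_prob:
                        losses.add(child)
                    else:
                        stack.append(child)
            truth.origin[hg] = origin
            truth.losses[hg] = frozenset(losses)
            truth.possessors[hg] = frozenset(np.array(tree.leaf_names)[mask])
            hg_ids.append(hg)
            rows.append(mask.astype(np.int64))

    counts = np.vstack(rows) if rows else np.zeros((0, tree.n_leaves), dtype=np.int64)
    occ = pd.DataFrame(
        counts, index=pd.Index(hg_ids, name="hg"), columns=list(tree.leaf_names)
    )
    return occ, truth


def apply_incompleteness(
    occ: pd.DataFrame,
    missing_rate: float | Mapping[str, float],
    seed: int = 0,
) -> pd.DataFrame:
    """Zero each present (HG, species) cell independently with the species'
    missing rate — BUSCO-style genome incompleteness. Counts never increase.

    ``missing_rate`` is a single rate for all species or a mapping
    species → rate (unmapped species keep rate 0).
    """
    if isinstance(missing_rate, Mapping):
        rates = {sp: float(missing_rate.get(sp, 0.0)) for sp in occ.columns}
    else:
        rates = {sp: float(missing_rate) for sp in occ.columns}
    bad = [sp for sp, r in rates.items() if not 0.0 <= r <= 1.0]
    if bad:
        raise InputError(f"missing rate outside [0, 1] for: {', '.join(bad)}")

    rng = np.random.default_rng(seed)
    out = occ.copy()
    for sp in occ.columns:
        rate = rates[sp]
        if rate == 0.0:
            continue
        col = out[sp].to_numpy().copy()
        present = np.flatnonzero(col > 0)
        dropped = present[rng.random(present.size) < rate]
        col[dropped] = 0
        out[sp] = col
    return out


# ----------------------------------------------------------- planted partition


@dataclass(frozen=True)
class PlantedGraphParams:
    """Planted-partition graph controls.

    cluster_sizes  node count per planted cluster (non-empty, positive)
    p_in / p_out   within- / between-cluster edge probabilities
    w_in / w_out   (low, high) uniform weight ranges for within / between
                   edges, on the −log10 e-value scale
    seed           RNG seed
    """

    cluster_sizes: tuple[int, ...] = (50,) * 20
    p_in: float = 0.3
    p_out: float = 0.01
    w_in: tuple[float, float] = (20.0, 100.0)
    w_out: tuple[float, float] = (2.0, 9.0)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "cluster_sizes", tuple(self.cluster_sizes))
        if not self.cluster_sizes:
            raise InputError("cluster_sizes must be non-empty")
        if any(int(s) != s or s < 1 for s in self.cluster_sizes):
            raise InputError("cluster sizes must be positive integers")
        for name, p in (("p_in", self.p_in), ("p_out", self.p_out)):
            if not 0.0 <= p <= 1.0:
                raise InputError(f"{name} must be in [0, 1]")
        for name, rng_ in (("w_in", self.w_in), ("w_out", self.w_out)):
            if len(rng_) != 2 or rng_[0] < 0 or rng_[1] < rng_[0]:
                raise InputError(f"{name} must be (low, high) with 0 <= low <= high")


def generate_planted_graph(
    params: PlantedGraphParams,
) -> tuple[nx.Graph, np.ndarray]:
    """Sample a weighted planted-partition graph.

    Returns the graph (node IDs ``n0000``, ...; edge attribute ``weight``)
    and the true cluster label per node, in node-ID order. Each unordered
    node pair receives an edge independently with ``p_in`` (same cluster) or
    ``p_out`` (different clusters).
    """
    rng = np.random.default_rng(params.seed)
    sizes = params.cluster_sizes
    n = sum(sizes)
    width = max(4, len(str(n - 1)))
    names = [f"n{i:0{width}d}" for i in range(n)]
    labels = np.repeat(np.arange(len(sizes)), sizes)

    graph = nx.Graph()
    graph.add_nodes_from(names)
    offsets = np.concatenate(([0], np.cumsum(sizes)))
    for ci, size in enumerate(sizes):
        a = offsets[ci]
        iu, ju = np.triu_indices(size, k=1)
        hit = rng.random(iu.size) < params.p_in
        w = rng.uniform(params.w_in[0], params.w_in[1], size=iu.size)
        for i, j, wt in zip(iu[hit] + a, ju[hit] + a, w[hit]):
            graph.add_edge(names[i], names[j], weight=float(wt))
        for cj in range(ci + 1, len(sizes)):
            b = offsets[cj]
            block = rng.random((size, sizes[cj])) < params.p_out
            w = rng.uniform(params.w_out[0], params.w_out[1], size=block.shape)
            for i, j in zip(*np.nonzero(block)):
                graph.add_edge(
                    names[a + i], names[b + j], weight=float(w[i, j])
                )
    return graph, labels


def write_synthetic_blast(
    graph: nx.Graph, path_or_handle, weight_cap: float = 200.0
) -> None:
    """Serialise a similarity graph as 12-column BLAST ``-outfmt 6`` lines,
    one hit per edge, with e-value = 10^(−weight).

    Weights at or above ``weight_cap`` are not invertible (the forward
    transform saturates) and are written at e-value 0. Unused columns carry
    valid placeholders. Parsing the stream back and rebuilding the graph
    reproduces it up to symmetrisation.
    """
    if isinstance(path_or_handle, (str, PathLike)):
        with open(path_or_handle, "w") as fh:
            write_synthetic_blast(graph, fh, weight_cap)
        return
    fh = path_or_handle
    for u, v in sorted(graph.edges):
        w = float(graph[u][v].get("weight", 1.0))
        evalue = weight_to_evalue(w, weight_cap)
        bitscore = 30.0 + 2.0 * min(w, weight_cap)
        fh.write(
            f"{u}\t{v}\t75.00\t100\t25\t0\t1\t100\t1\t100\t"
            f"{evalue!r}\t{bitscore:.1f}\n"
        )
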