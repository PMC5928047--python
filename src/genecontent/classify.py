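"""Dollo-style classification of homology-group inventories on a species tree.

The model: a homology group (HG) arises exactly once and can only be lost
thereafter. Given an HG × species occupancy matrix (presence = count >= 1)
and a rooted tree with named internal nodes, every node's inventory is
split into:

* **Ancestral** — HGs inferred present in the node's last common ancestor.
  Two operational readings are provided. ``"dollo"``: the node lies on the
  minimal-loss single-gain reconstruction (possessors inside the clade, and
  either >= 2 occupied child subtrees or possessors outside the clade).
  ``"two_lineage"`` (default): possessors occupy at least two of the node's
  child subtrees — presence witnessed independently by two main lineages,
  which makes the call robust to a single incomplete genome.
* **Novel** — HGs whose origin is exactly this node: possessors occupy >= 2
  child subtrees and no leaf outside the clade. Mode-independent; equals
  "MRCA of possessors = node". At a leaf: HGs exclusive to that species.
* **Core** (Ancestral Core / Novel Core) — the subset absent from at most
  ``allowed_absences`` clade members (default 1, accommodating genome
  incompleteness) while keeping every child lineage occupied.
* **Lost** — HGs absent from the entire clade yet present in the parent
  lineage, witnessed by a sibling subtree possessor and a possessor outside
  the parent's clade. For children of the root no outside witness can
  exist; their Lost set is defined empty (logged once per run).

Copy numbers are carried through for reporting but never affect
classification; only presence/absence matters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import InputError
from .trees import SpeciesTree

__all__ = [
    "NodeCategories",
    "NodeClassification",
    "mrca",
    "presence_at_node",
    "ancestral_hgs",
    "novel_hgs",
    "core_filter",
    "lost_hgs",
    "classify_all",
    "summarize",
    "percentage",
    "integer_percentage",
]

logger = logging.getLogger(__name__)

MODES = ("dollo", "two_lineage")

CATEGORIES = ("ancestral", "novel", "novel_core", "ancestral_core", "lost")


# ----------------------------------------------------------------- containers


@dataclass(frozen=True)
class NodeCategories:
    """The five HG sets of one tree node."""

    ancestral: frozenset[str]
    novel: frozenset[str]
    novel_core: frozenset[str]
    ancestral_core: frozenset[str]
    lost: frozenset[str]

    def get(self, category: str) -> frozenset[str]:
        if category not in CATEGORIES:
            raise InputError(f"unknown category {category!r}")
        return getattr(self, category)


class NodeClassification:
    """Per-node classification for a whole tree."""

    def __init__(
        self,
        by_node: Mapping[str, NodeCategories],
        mode: str,
        allowed_absences: int,
        tree: SpeciesTree,
    ):
        self._by_node = dict(by_node)
        self.mode = mode
        self.allowed_absences = allowed_absences
        self.tree = tree

    def __getitem__(self, node: str) -> NodeCategories:
        try:
            return self._by_node[node]
        except KeyError:
            raise InputError(f"unknown node {node!r}") from None

    def __contains__(self, node: str) -> bool:
        return node in self._by_node

    def nodes(self) -> tuple[str, ...]:
        """Node labels in tree preorder."""
        return tuple(l for l in self.tree.labels if l in self._by_node)

    def items(self) -> Iterator[tuple[str, NodeCategories]]:
        for node in self.nodes():
            yield node, self._by_node[node]

    def to_long_frame(self) -> pd.DataFrame:
        """Long format: one row per (node, category, HG)."""
        records = []
        for node, cats in self.items():
            for category in CATEGORIES:
                for hg in sorted(cats.get(category)):
                    records.append((node, category, hg))
        return pd.DataFrame(records, columns=["node", "category", "hg"])


# ----------------------------------------------------------------- primitives


def mrca(tree: SpeciesTree, leaf_set: Iterable[str]) -> str:
    """Most recent common ancestor of a leaf set (the HG's inferred origin
    under the single-gain assumption)."""
    return tree.mrca(leaf_set)


def presence_at_node(
    tree: SpeciesTree,
    possessors: Iterable[str],
    node: str,
    mode: str = "dollo",
) -> bool:
    """Is an HG with the given possessor leaves inferred present at ``node``?

    ``dollo``: node is inside the minimal-loss single-gain reconstruction.
    ``two_lineage``: possessors occupy >= 2 of the node's child subtrees.
    At a leaf (either mode): presence means the leaf possesses the HG.
    """
    if mode not in MODES:
        raise InputError(f"unknown mode {mode!r}; expected one of {MODES}")
    possessors = set(possessors)
    unknown = sorted(p for p in possessors if p not in tree.leaf_names)
    if unknown:
        raise InputError(f"unknown possessor leaves: {', '.join(unknown)}")
    if tree.is_leaf(node):
        return node in possessors
    inside = possessors & tree.leaf_set(node)
    if not inside:
        return False
    occupied_children = sum(
        1 for c in tree.children(node) if possessors & tree.leaf_set(c)
    )
    if mode == "two_lineage":
        return occupied_children >= 2
    outside = possessors - tree.leaf_set(node)
    return occupied_children >= 2 or bool(outside)


# ------------------------------------------------------- vectorised internals


def _aligned_presence(
    tree: SpeciesTree, occ: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """(HG IDs, HG × leaf boolean presence) with columns in tree leaf order.

    The occupancy species set must equal the tree leaf set; offenders are
    listed in the error.
    """
    occ_species = set(map(str, occ.columns))
    tree_species = set(tree.leaf_names)
    extra = sorted(occ_species - tree_species)
    missing = sorted(tree_species - occ_species)
    if extra or missing:
        parts = []
        if extra:
            parts.append(f"species in occupancy but not tree: {', '.join(extra)}")
        if missing:
            parts.append(f"tree leaves missing from occupancy: {', '.join(missing)}")
        raise InputError("; ".join(parts))
    aligned = occ[list(tree.leaf_names)]
    return np.asarray(occ.index, dtype=object), aligned.to_numpy() >= 1


def _presence_counts(tree: SpeciesTree, P: np.ndarray) -> np.ndarray:
    """cnt[node, hg] = number of possessor species inside the node's clade."""
    n_nodes = len(tree.labels)
    cnt = np.zeros((n_nodes, P.shape[0]), dtype=np.int32)
    children = tree._children  # flat indices, preorder
    for i in range(n_nodes - 1, -1, -1):
        if not children[i]:
            cnt[i] = P[:, tree.leaf_column(tree.labels[i])]
        else:
            for c in children[i]:
                cnt[i] += cnt[c]
    return cnt


def _require_internal(tree: SpeciesTree, node: str, op: str) -> None:
    if tree.is_leaf(node):
        raise InputError(
            f"{op} is defined for internal nodes; for the species {node!r} "
            "use per-leaf presence (occupancy count >= 1)"
        )


# ----------------------------------------------------------- per-node queries


def ancestral_hgs(
    tree: SpeciesTree, occ: pd.DataFrame, node: str, mode: str = "two_lineage"
) -> frozenset[str]:
    """HGs inferred present at an internal node under the chosen mode."""
    if mode not in MODES:
        raise InputError(f"unknown mode {mode!r}; expected one of {MODES}")
    _require_internal(tree, node, "ancestral_hgs")
    hg_ids, P = _aligned_presence(tree, occ)
    cnt = _presence_counts(tree, P)
    i = tree._idx(node)
    k_occ = np.zeros(P.shape[0], dtype=np.int32)
    for c in tree._children[i]:
        k_occ += cnt[c] > 0
    if mode == "two_lineage":
        keep = k_occ >= 2
    else:
        total = cnt[0]
        keep = (cnt[i] > 0) & ((k_occ >= 2) | (total > cnt[i]))
    return frozenset(hg_ids[keep])


def novel_hgs(tree: SpeciesTree, occ: pd.DataFrame, node: str) -> frozenset[str]:
    """HGs originating exactly at ``node``: possessors occupy >= 2 child
    subtrees and nothing outside the clade (equivalently, the MRCA of the
    possessors is ``node``). At a leaf: HGs exclusive to that species."""
    hg_ids, P = _aligned_presence(tree, occ)
    cnt = _presence_counts(tree, P)
    total = cnt[0]
    i = tree._idx(node)
    if tree.is_leaf(node):
        keep = (cnt[i] > 0) & (cnt[i] == total)
    else:
        k_occ = np.zeros(P.shape[0], dtype=np.int32)
        for c in tree._children[i]:
            k_occ += cnt[c] > 0
        keep = (k_occ >= 2) & (cnt[i] == total)
    return frozenset(hg_ids[keep])


def core_filter(
    tree: SpeciesTree,
    occ: pd.DataFrame,
    node: str,
    hg_set: Iterable[str],
    allowed_absences: int = 1,
    require_two_lineages: bool = True,
) -> frozenset[str]:
    """Restrict ``hg_set`` to HGs absent from at most ``allowed_absences``
    clade members and (by default) still present in every child lineage.

    The one-absence allowance makes "core" calls robust to a single
    incomplete genome; the child-lineage condition keeps the presence call
    witnessed by the clade's main lineages."""
    if allowed_absences < 0:
        raise InputError("allowed_absences must be >= 0")
    _require_internal(tree, node, "core_filter")
    hg_set = frozenset(hg_set)
    hg_ids, P = _aligned_presence(tree, occ)
    cnt = _presence_counts(tree, P)
    i = tree._idx(node)
    clade_size = int(tree.leaf_mask(node).sum())
    ok = (clade_size - cnt[i]) <= allowed_absences
    if require_two_lineages:
        for c in tree._children[i]:
            ok &= cnt[c] > 0
    kept = frozenset(hg_ids[ok])
    return hg_set & kept


def lost_hgs(tree: SpeciesTree, occ: pd.DataFrame, node: str) -> frozenset[str]:
    """HGs lost on the branch leading to ``node``: absent from the whole
    clade, but present in a sibling subtree and outside the parent's clade
    (so Dollo presence at the parent is witnessed).

    The root has no parent (error); children of the root have no possible
    outside-parent witness and return the empty set with a logged warning."""
    parent = tree.parent(node)
    if parent is None:
        raise InputError("lost_hgs is undefined at the root (no parent branch)")
    if parent == tree.root:
        logger.warning(
            "Lost set for %r is defined empty: its parent is the root, so "
            "no outgroup can witness parental presence",
            node,
        )
        return frozenset()
    hg_ids, P = _aligned_presence(tree, occ)
    cnt = _presence_counts(tree, P)
    total = cnt[0]
    i, p = tree._idx(node), tree._idx(parent)
    keep = (cnt[i] == 0) & (cnt[p] > cnt[i]) & (total > cnt[p])
    return frozenset(hg_ids[keep])


# ------------------------------------------------------------- full classifier


def classify_all(
    tree: SpeciesTree,
    occ: pd.DataFrame,
    mode: str = "two_lineage",
    allowed_absences: int = 1,
    require_two_lineages: bool = True,
) -> NodeClassification:
    """Classify every node's HG inventory in one vectorised pass.

    Leaves get their present HGs as ``ancestral``, species-exclusive HGs as
    ``novel``, and empty core sets (core is undefined for a single genome).
    In dollo mode the result satisfies, for internal nodes whose parent is
    not the root, the recurrence
    ``ancestral(C) = (ancestral(parent) \\ lost(C)) ⊎ novel(C)``.
    """
    if mode not in MODES:
        raise InputError(f"unknown mode {mode!r}; expected one of {MODES}")
    if allowed_absences < 0:
        raise InputError("allowed_absences must be >= 0")
    hg_ids, P = _aligned_presence(tree, occ)
    cnt = _presence_counts(tree, P)
    total = cnt[0]
    children = tree._children
    clade_sizes = tree._leaf_masks.sum(axis=1)

    root_warned = False
    by_node: dict[str, NodeCategories] = {}
    for i, label in enumerate(tree.labels):
        inside = cnt[i] > 0
        if not children[i]:
            ancestral = inside
            novel = inside & (cnt[i] == total)
            novel_core = np.zeros_like(inside)
            ancestral_core = np.zeros_like(inside)
        else:
            k_occ = np.zeros(P.shape[0], dtype=np.int32)
            all_children = np.ones(P.shape[0], dtype=bool)
            for c in children[i]:
                occ_c = cnt[c] > 0
                k_occ += occ_c
                all_children &= occ_c
            if mode == "two_lineage":
                ancestral = k_occ >= 2
            else:
                ancestral = inside & ((k_occ >= 2) | (total > cnt[i]))
            novel = (k_occ >= 2) & (cnt[i] == total)
            core_ok = (clade_sizes[i] - cnt[i]) <= allowed_absences
            if require_two_lineages:
                core_ok = core_ok & all_children
            novel_core = novel & core_ok
            ancestral_core = ancestral & core_ok

        parent = tree._parent[i]
        if parent < 0:
            lost = np.zeros_like(inside)
        elif parent == 0:
            if not root_warned:
                logger.warning(
                    "Lost sets for children of the root are defined empty: no "
                    "outgroup exists to witness parental presence"
                )
                root_warned = True
            lost = np.zeros_like(inside)
        else:
            lost = (cnt[i] == 0) & (cnt[parent] > 0) & (total > cnt[parent])

        by_node[label] = NodeCategories(
            ancestral=frozenset(hg_ids[ancestral]),
            novel=frozenset(hg_ids[novel]),
            novel_core=frozenset(hg_ids[novel_core]),
            ancestral_core=frozenset(hg_ids[ancestral_core]),
            lost=frozenset(hg_ids[lost]),
        )
    return NodeClassification(by_node, mode, allowed_absences, tree)


# -------------------------------------------------------------------- summary


def percentage(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """100·numerator/denominator rounded to ``ndigits``; NaN when the
    denominator is zero (undefined, never reported as 0%)."""
    if denominator == 0:
        return float("nan")
    return round(100.0 * numerator / denominator, ndigits)


def integer_percentage(numerator: int, denominator: int) -> float:
    """Nearest-integer percentage (NaN when undefined), mirroring prose-style
    reporting such as "19% of the HG"."""
    if denominator == 0:
        return float("nan")
    return float(int(np.round(100.0 * numerator / denominator)))


def summarize(classification: NodeClassification) -> pd.DataFrame:
    """Per-node counts and derived fractions, one row per node in preorder.

    Columns: the five set sizes; ``novel_fraction_pct`` = 100·|novel|/|ancestral|
    (1 decimal) with an integer-rounded twin; ``core_novel_fraction_pct`` =
    100·|novel_core|/|ancestral_core|; ``novel_retention_pct`` =
    100·|novel_core|/|novel|. Undefined fractions are NaN."""
    tree = classification.tree
    rows = []
    for node, cats in classification.items():
        n_anc = len(cats.ancestral)
        n_nov = len(cats.novel)
        n_nc = len(cats.novel_core)
        n_ac = len(cats.ancestral_core)
        rows.append(
            {
                "node": node,
                "is_leaf": tree.is_leaf(node),
                "n_ancestral": n_anc,
                "n_novel": n_nov,
                "n_novel_core": n_nc,
                "n_ancestral_core": n_ac,
                "n_lost": len(cats.lost),
                "novel_fraction_pct": percentage(n_nov, n_anc),
                "novel_fraction_int_pct": integer_percentage(n_nov, n_anc),
                "core_novel_fraction_pct": percentage(n_nc, n_ac),
                "novel_retention_pct": percentage(n_nc, n_nov),
            }
        )
    return pd.DataFrame(rows)
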