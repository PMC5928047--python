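"""Rooted species trees with uniquely named leaves and internal nodes.

Newick parsing is delegated to dendropy; the parsed topology is then frozen
into flat arrays (preorder label list, parent indices, per-node boolean leaf
masks) so that gene-content classification over tens of thousands of homology
groups can be vectorised with numpy instead of walking the tree per group.

Internal nodes without a Newick label are auto-named ``N<preorder index>``,
deterministically, so every clade can be addressed by name in queries and
reports.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np

from .errors import TreeError

__all__ = ["SpeciesTree", "random_binary_tree"]


class SpeciesTree:
    """A rooted tree over species (leaves) and named clades (internal nodes).

    Nodes are addressed by label. Leaves are species names; internal labels
    are clade names (e.g. ``Metazoa``). All labels are unique. Internal nodes
    have at least two children (polytomies allowed); unifurcations are
    rejected.
    """

    def __init__(
        self,
        labels: Sequence[str],
        parent_idx: Sequence[int],
        children_idx: Sequence[Sequence[int]],
    ):
        self._labels: tuple[str, ...] = tuple(labels)
        self._parent = np.asarray(parent_idx, dtype=np.int64)
        self._children: tuple[tuple[int, ...], ...] = tuple(
            tuple(c) for c in children_idx
        )
        if len(set(self._labels)) != len(self._labels):
            seen, dups = set(), set()
            for lab in self._labels:
                (dups if lab in seen else seen).add(lab)
            raise TreeError(f"duplicate node labels: {', '.join(sorted(dups))}")
        self._index = {lab: i for i, lab in enumerate(self._labels)}

        leaf_order = [i for i in range(len(self._labels)) if not self._children[i]]
        self._leaf_names: tuple[str, ...] = tuple(self._labels[i] for i in leaf_order)
        self._leaf_col = {self._labels[i]: j for j, i in enumerate(leaf_order)}
        if len(self._leaf_names) < 2:
            raise TreeError("tree must have at least 2 leaves")

        n, m = len(self._labels), len(self._leaf_names)
        masks = np.zeros((n, m), dtype=bool)
        # reversed preorder => children are filled before their parent
        for i in range(n - 1, -1, -1):
            if not self._children[i]:
                masks[i, self._leaf_col[self._labels[i]]] = True
            else:
                for c in self._children[i]:
                    masks[i] |= masks[c]
        masks.setflags(write=False)
        self._leaf_masks = masks

    # ---------------------------------------------------------------- parsing

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        """Parse a rooted Newick string, auto-naming unlabeled internal nodes."""
        try:
            dtree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise TreeError(f"could not parse Newick: {exc}") from exc

        labels: list[str] = []
        parent_idx: list[int] = []
        children_idx: list[list[int]] = []
        node_to_idx: dict[int, int] = {}

        for node in dtree.preorder_node_iter():
            idx = len(labels)
            node_to_idx[id(node)] = idx
            kids = node.child_nodes()
            if len(kids) == 1:
                raise TreeError("unifurcation (internal node with one child)")
            if kids:
                label = node.label
                if label is None or label == "":
                    label = f"N{idx}"
            else:
                label = node.taxon.label if node.taxon is not None else node.label
                if not label:
                    raise TreeError("leaf without a name")
            labels.append(label)
            parent_idx.append(
                node_to_idx[id(node.parent_node)] if node.parent_node else -1
            )
            children_idx.append([])
            if node.parent_node is not None:
                children_idx[node_to_idx[id(node.parent_node)]].append(idx)
        return cls(labels, parent_idx, children_idx)

    @classmethod
    def from_file(cls, path) -> "SpeciesTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        def render(i: int) -> str:
            if not self._children[i]:
                return self._labels[i]
            inner = ",".join(render(c) for c in self._children[i])
            return f"({inner}){self._labels[i]}"

        return render(0) + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # ------------------------------------------------------------- structure

    @property
    def labels(self) -> tuple[str, ...]:
        """All node labels in preorder (root first)."""
        return self._labels

    @property
    def root(self) -> str:
        return self._labels[0]

    @property
    def leaf_names(self) -> tuple[str, ...]:
        """Leaf labels in preorder (left-to-right Newick order)."""
        return self._leaf_names

    @property
    def internal_labels(self) -> tuple[str, ...]:
        return tuple(lab for i, lab in enumerate(self._labels) if self._children[i])

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_names)

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __len__(self) -> int:
        return len(self._labels)

    def _idx(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise TreeError(f"unknown node label: {label!r}") from None

    def is_leaf(self, label: str) -> bool:
        return not self._children[self._idx(label)]

    def children(self, label: str) -> tuple[str, ...]:
        return tuple(self._labels[c] for c in self._children[self._idx(label)])

    def parent(self, label: str) -> str | None:
        p = self._parent[self._idx(label)]
        return None if p < 0 else self._labels[p]

    def siblings(self, label: str) -> tuple[str, ...]:
        p = self.parent(label)
        if p is None:
            return ()
        return tuple(c for c in self.children(p) if c != label)

    def leaf_mask(self, label: str) -> np.ndarray:
        """Read-only boolean mask over ``leaf_names`` for the node's clade."""
        return self._leaf_masks[self._idx(label)]

    def leaf_set(self, label: str) -> frozenset[str]:
        mask = self.leaf_mask(label)
        return frozenset(
            name for name, m in zip(self._leaf_names, mask) if m
        )

    def leaf_column(self, species: str) -> int:
        try:
            return self._leaf_col[species]
        except KeyError:
            raise TreeError(f"unknown species: {species!r}") from None

    def preorder(self) -> Iterator[str]:
        return iter(self._labels)

    # ------------------------------------------------------------------ mrca

    def mrca(self, leaves: Iterable[str]) -> str:
        """Most recent common ancestor: the deepest node whose clade contains
        every requested leaf. A single leaf is its own MRCA."""
        leaves = list(leaves)
        if not leaves:
            raise TreeError("mrca of an empty leaf set")
        unknown = sorted(l for l in leaves if l not in self._leaf_col)
        if unknown:
            raise TreeError(f"unknown leaves: {', '.join(unknown)}")
        target = np.zeros(self.n_leaves, dtype=bool)
        for l in leaves:
            target[self._leaf_col[l]] = True

        i = 0
        while True:
            for c in self._children[i]:
                if (target & ~self._leaf_masks[c]).sum() == 0:
                    i = c
                    break
            else:
                return self._labels[i]


def random_binary_tree(
    n_leaves: int, seed: int, leaf_prefix: str = "sp"
) -> SpeciesTree:
    """Random rooted binary topology built by successive joins of a uniformly
    chosen pair of subtrees. Leaves are ``sp000, sp001, ...``; internal nodes
    get deterministic auto-names. Same seed ⇒ same tree."""
    if n_leaves < 2:
        raise TreeError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    items = [f"{leaf_prefix}{i:03d}" for i in range(n_leaves)]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        b = items.pop(int(j))
        a = items.pop(int(i))
        items.append(f"({a},{b})")
    return SpeciesTree.from_newick(items[0] + ";")
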