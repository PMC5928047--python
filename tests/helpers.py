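"""Shared test helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd

from genecontent import HomologyGroupSet, SpeciesTree


def occ_from_patterns(tree: SpeciesTree, patterns: dict[str, set[str]]) -> pd.DataFrame:
    """Occupancy matrix (0/1) from HG → possessor-leaf-set patterns."""
    cols = list(tree.leaf_names)
    data = [[1 if sp in poss else 0 for sp in cols] for poss in patterns.values()]
    return pd.DataFrame(
        data, index=pd.Index(list(patterns), name="hg"), columns=cols
    )


def partition_labels(hgset: HomologyGroupSet, node_order: list[str]) -> np.ndarray:
    """Integer cluster label per node, in the given node order."""
    idx = {n: i for i, n in enumerate(node_order)}
    labels = np.empty(len(node_order), dtype=int)
    for ci, (_, members) in enumerate(hgset):
        for m in members:
            labels[idx[m]] = ci
    return labels


def all_possessor_patterns(tree: SpeciesTree):
    """Every non-empty subset of the tree's leaves."""
    leaves = list(tree.leaf_names)
    n = len(leaves)
    for bits in range(1, 2**n):
        yield frozenset(l for i, l in enumerate(leaves) if bits >> i & 1)
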