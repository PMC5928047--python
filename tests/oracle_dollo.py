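"""Independent brute-force oracle for single-gain / minimal-loss
classification.

For each homology group it enumerates every candidate origin node whose
clade contains all possessors, scores the implied scenario by its number of
loss events, and keeps the minimal-loss one. Categories are then read
directly off the reconstruction. Pure-python recursion per HG — slow but
transparent, and entirely independent of the vectorised production code.
"""

from __future__ import annotations

from genecontent import SpeciesTree


def clade_nodes(tree: SpeciesTree, node: str) -> list[str]:
    """node plus all its descendants."""
    out = [node]
    for child in tree.children(node):
        out.extend(clade_nodes(tree, child))
    return out


def minimal_loss_scenarios(tree: SpeciesTree, possessors: frozenset[str]):
    """All minimal-loss single-gain scenarios as (losses, origin, present set)."""
    scenarios = []
    for origin in tree.labels:
        if not possessors <= tree.leaf_set(origin):
            continue
        nodes = clade_nodes(tree, origin)
        present = {
            n for n in nodes if possessors & tree.leaf_set(n)
        } | {origin}
        losses = sum(
            1
            for n in nodes
            if n != origin and tree.parent(n) in present and n not in present
        )
        scenarios.append((losses, origin, frozenset(present)))
    best = min(s[0] for s in scenarios)
    return [s for s in scenarios if s[0] == best]


def oracle_classify(
    tree: SpeciesTree,
    patterns: dict[str, frozenset[str]],
    allowed_absences: int = 1,
):
    """Per-node category sets from the brute-force reconstruction.

    Returns dict node -> dict with keys ancestral_dollo,
    ancestral_two_lineage, novel, novel_core, ancestral_core_dollo,
    ancestral_core_two_lineage, lost.
    """
    keys = (
        "ancestral_dollo",
        "ancestral_two_lineage",
        "novel",
        "novel_core",
        "ancestral_core_dollo",
        "ancestral_core_two_lineage",
        "lost",
    )
    result = {n: {k: set() for k in keys} for n in tree.labels}

    for hg, possessors in patterns.items():
        possessors = frozenset(possessors)
        if not possessors:
            continue
        scenarios = minimal_loss_scenarios(tree, possessors)
        # single-gain Dollo: the minimal scenario must be unique, gained at
        # the MRCA of the possessors
        assert len(scenarios) == 1, (possessors, scenarios)
        _, origin, present = scenarios[0]
        assert origin == tree.mrca(possessors)

        for node in tree.labels:
            inside = possessors & tree.leaf_set(node)
            if tree.is_leaf(node):
                if inside:
                    result[node]["ancestral_dollo"].add(hg)
                    result[node]["ancestral_two_lineage"].add(hg)
                if origin == node:
                    result[node]["novel"].add(hg)
            else:
                occupied = [
                    c
                    for c in tree.children(node)
                    if possessors & tree.leaf_set(c)
                ]
                absences = len(tree.leaf_set(node)) - len(inside)
                core_ok = absences <= allowed_absences and len(occupied) == len(
                    tree.children(node)
                )
                if node in present:
                    result[node]["ancestral_dollo"].add(hg)
                    if core_ok:
                        result[node]["ancestral_core_dollo"].add(hg)
                if len(occupied) >= 2:
                    result[node]["ancestral_two_lineage"].add(hg)
                    if core_ok:
                        result[node]["ancestral_core_two_lineage"].add(hg)
                if origin == node:
                    result[node]["novel"].add(hg)
                    if core_ok:
                        result[node]["novel_core"].add(hg)
            parent = tree.parent(node)
            if (
                parent is not None
                and parent != tree.root
                and parent in present
                and not inside
            ):
                result[node]["lost"].add(hg)
    return result
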