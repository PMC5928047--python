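"""Clade-quantifier queries over an occupancy matrix.

A query is a conjunction of clauses, each a presence quantifier applied to a
clade (any tree node, species included) or its complement:

    all(Metazoa) & none(!Metazoa)
    all_minus(Arthropoda,1)
    any(Homo_sapiens) & at_least(Hexapoda,2) & none(Lophotrochozoa)

Quantifiers: ``all``, ``none``, ``any``, ``at_least(C,k)``, ``exactly(C,k)``
and ``all_minus(C,k)`` (present in all members of C except at most k).
``!C`` denotes the complement of C's leaf set. A clause counts the species
of its (possibly complemented) leaf set whose occupancy count is >= 1.

The grammar is conjunction-only; every example query the classifier needs
(novelty, core rules, exclusivity) is expressible and auditable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import _aligned_presence
from .errors import QueryError
from .trees import SpeciesTree

__all__ = ["QueryClause", "Query", "parse_query", "evaluate_query"]

QUANTIFIERS = ("all", "none", "any", "at_least", "exactly", "all_minus")
_K_QUANTIFIERS = ("at_least", "exactly", "all_minus")

_CLAUSE_RE = re.compile(
    r"\s*(?P<quant>[A-Za-z_]+)\s*\(\s*(?P<comp>!?)\s*(?P<clade>[^,()!\s]+)\s*"
    r"(?:,\s*(?P<k>\d+)\s*)?\)\s*"
)


@dataclass(frozen=True)
class QueryClause:
    """One quantified clade condition."""

    quantifier: str
    clade: str
    complement: bool = False
    k: int | None = None

    def render(self) -> str:
        clade = ("!" if self.complement else "") + self.clade
        if self.k is None:
            return f"{self.quantifier}({clade})"
        return f"{self.quantifier}({clade},{self.k})"


@dataclass(frozen=True)
class Query:
    """A conjunction of clauses."""

    clauses: tuple[QueryClause, ...]

    def render(self) -> str:
        return " & ".join(c.render() for c in self.clauses)


def _clause_leaf_mask(tree: SpeciesTree, clause: QueryClause) -> np.ndarray:
    mask = tree.leaf_mask(clause.clade)
    return ~mask if clause.complement else mask


def parse_query(text: str, tree: SpeciesTree) -> Query:
    """Parse and validate a query against a tree.

    Unknown clade labels, bad arity and out-of-range ``k`` raise
    :class:`QueryError`; syntax errors report the character position."""
    clauses: list[QueryClause] = []
    pos = 0
    n = len(text)
    if not text.strip():
        raise QueryError("empty query")
    while pos < n:
        m = _CLAUSE_RE.match(text, pos)
        if not m:
            raise QueryError(
                f"syntax error at position {pos}: expected "
                f"quantifier(clade[,k]) in {text[pos:pos + 30]!r}"
            )
        quant = m.group("quant")
        if quant not in QUANTIFIERS:
            raise QueryError(
                f"position {m.start('quant')}: unknown quantifier {quant!r} "
                f"(expected one of {', '.join(QUANTIFIERS)})"
            )
        clade = m.group("clade")
        if clade not in tree:
            raise QueryError(f"unknown clade label: {clade!r}")
        k_text = m.group("k")
        if quant in _K_QUANTIFIERS:
            if k_text is None:
                raise QueryError(f"{quant} requires a count, e.g. {quant}({clade},1)")
            k = int(k_text)
        else:
            if k_text is not None:
                raise QueryError(f"{quant} takes no count argument")
            k = None
        clause = QueryClause(quant, clade, complement=bool(m.group("comp")), k=k)
        if k is not None:
            size = int(_clause_leaf_mask(tree, clause).sum())
            if k > size:
                raise QueryError(
                    f"{clause.render()}: count {k} exceeds clade size {size}"
                )
        clauses.append(clause)
        pos = m.end()
        if pos < n:
            if text[pos] != "&":
                raise QueryError(
                    f"syntax error at position {pos}: expected '&', "
                    f"found {text[pos]!r}"
                )
            pos += 1
            if pos >= n or not text[pos:].strip():
                raise QueryError(f"dangling '&' at position {pos - 1}")
    return Query(tuple(clauses))


def evaluate_query(
    query: Query, occ: pd.DataFrame, tree: SpeciesTree
) -> list[str]:
    """HG IDs satisfying every clause, sorted.

    Each clause counts clade species with occupancy count >= 1:
    ``all`` ⇔ count = clade size, ``none`` ⇔ 0, ``any`` ⇔ >= 1,
    ``at_least(k)`` ⇔ >= k, ``exactly(k)`` ⇔ = k, ``all_minus(k)`` ⇔
    >= clade size − k. Empty clades satisfy ``all`` and ``none`` vacuously.
    """
    hg_ids, P = _aligned_presence(tree, occ)
    keep = np.ones(P.shape[0], dtype=bool)
    for clause in query.clauses:
        mask = _clause_leaf_mask(tree, clause)
        size = int(mask.sum())
        counts = P[:, mask].sum(axis=1)
        if clause.quantifier == "all":
            keep &= counts == size
        elif clause.quantifier == "none":
            keep &= counts == 0
        elif clause.quantifier == "any":
            keep &= counts >= 1
        elif clause.quantifier == "at_least":
            keep &= counts >= clause.k
        elif clause.quantifier == "exactly":
            keep &= counts == clause.k
        elif clause.quantifier == "all_minus":
            keep &= counts >= size - clause.k
    return sorted(hg_ids[keep])
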