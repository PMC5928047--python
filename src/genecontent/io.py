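"""Readers and writers for the package's tabular interchange formats.

Occupancy matrices travel as TSV: first column is the homology-group (HG)
ID, remaining columns are species names, and cells are non-negative integer
gene counts (presence = count >= 1). Protein→species maps are 2-column TSV.
"""

from __future__ import annotations

from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "read_occupancy",
    "write_occupancy",
    "read_species_map",
    "species_from_prefix",
    "resolve_species_of",
]


def read_occupancy(path) -> pd.DataFrame:
    """Read an HG × species count table (TSV, first column = HG ID)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise InputError(f"duplicate HG IDs in occupancy: {', '.join(map(str, dups))}")
    try:
        arr = df.to_numpy(dtype=np.int64)
    except (ValueError, TypeError) as exc:
        raise InputError(f"non-integer cell in occupancy table: {exc}") from exc
    if (arr < 0).any():
        raise InputError("negative gene count in occupancy table")
    df = pd.DataFrame(arr, index=df.index.astype(str), columns=df.columns.astype(str))
    df.index.name = "hg"
    return df


def write_occupancy(occ: pd.DataFrame, path) -> None:
    occ.to_csv(path, sep="\t", index_label="hg")


def read_species_map(path) -> dict[str, str]:
    """Read a 2-column TSV mapping protein ID → species name."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise InputError(
                    f"species map line {lineno}: expected 2 tab-separated columns"
                )
            pid, sp = parts
            if pid in mapping and mapping[pid] != sp:
                raise InputError(
                    f"species map line {lineno}: protein {pid!r} mapped twice"
                )
            mapping[pid] = sp
    return mapping


def species_from_prefix(delimiter: str = "|") -> Callable[[str], str]:
    """Species extractor for IDs of the form ``<species><delimiter><gene>``."""

    def extract(protein_id: str) -> str:
        if delimiter not in protein_id:
            raise InputError(
                f"protein ID {protein_id!r} has no species prefix "
                f"(delimiter {delimiter!r})"
            )
        return protein_id.split(delimiter, 1)[0]

    return extract


def resolve_species_of(
    species_of: Mapping[str, str] | Callable[[str], str],
) -> Callable[[str], str]:
    """Normalise a mapping or callable into a callable protein→species."""
    if callable(species_of):
        return species_of

    mapping = species_of

    def lookup(protein_id: str) -> str:
        try:
            return mapping[protein_id]
        except KeyError:
            raise InputError(f"protein {protein_id!r} missing from species map") from None

    return lookup
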