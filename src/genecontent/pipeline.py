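"""End-to-end pipeline: similarity hits → homology groups → occupancy →
per-node classification → reports.

A single :class:`PipelineConfig` (loadable from YAML, every field
overridable) captures all parameters so a run is reproducible from its
manifest. Outputs are plain TSV with one header line; reruns with the same
config and seed are byte-identical. Stage failures abort with the stage
name and the offending input in the message.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import pandas as pd
import yaml

from . import classify as _classify
from .clustering import (
    GraphBuildParams,
    HomologyGroupSet,
    MCLParams,
    build_similarity_graph,
    mcl_cluster,
    parse_blast_tab,
    read_clusters,
    write_clusters,
)
from .errors import GeneContentError, InputError
from .io import read_species_map, species_from_prefix, write_occupancy
from .trees import SpeciesTree

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "render_node_table"]

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "node",
    "n_ancestral",
    "n_novel",
    "n_novel_core",
    "n_lost",
    "n_ancestral_core",
    "novel_fraction_pct",
    "novel_fraction_int_pct",
    "core_novel_fraction_pct",
    "novel_retention_pct",
]


class PipelineError(GeneContentError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    Exactly one of ``blast`` (12-column tabular hits) or ``clusters``
    (one cluster per line) must be supplied. Species are taken from
    ``species_map`` (2-column TSV) if given, otherwise from the protein-ID
    prefix before ``species_delimiter``.
    """

    tree: str = ""
    out: str = ""
    blast: str | None = None
    clusters: str | None = None
    species_map: str | None = None
    species_delimiter: str = "|"
    evalue_max: float = 1e-5
    weight_cap: float = 200.0
    symmetrization: str = "max"
    inflation: float = 2.0
    expansion: int = 2
    prune_threshold: float = 1e-5
    mcl_tol: float = 1e-6
    mcl_max_iterations: int = 100
    mode: str = "two_lineage"
    allowed_absences: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InputError(f"config {path}: expected a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise InputError(f"config {path}: unknown keys {sorted(unknown)}")
        cfg = cls(**data)
        overrides = {k: v for k, v in overrides.items() if v is not None}
        return replace(cfg, **overrides)

    def validate(self) -> None:
        if not self.tree:
            raise InputError("config: 'tree' is required")
        if not self.out:
            raise InputError("config: 'out' is required")
        if (self.blast is None) == (self.clusters is None):
            raise InputError(
                "config: exactly one of 'blast' or 'clusters' must be supplied"
            )

    def graph_params(self) -> GraphBuildParams:
        return GraphBuildParams(
            evalue_max=self.evalue_max,
            weight_cap=self.weight_cap,
            symmetrization=self.symmetrization,
        )

    def mcl_params(self) -> MCLParams:
        return MCLParams(
            inflation=self.inflation,
            expansion=self.expansion,
            prune_threshold=self.prune_threshold,
            tol=self.mcl_tol,
            max_iterations=self.mcl_max_iterations,
        )


def _stage(name: str):
    class _Stage:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r}: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - self.t0)
            return False

    return _Stage()


def render_node_table(summary: pd.DataFrame) -> tuple[str, str]:
    """(TSV, human-readable text) node table: one row per internal node in
    preorder, the four headline counts first, undefined fractions as NA."""
    internal = summary.loc[~summary["is_leaf"], SUMMARY_COLUMNS].copy()
    tsv = internal.to_csv(sep="\t", index=False, float_format="%.1f", na_rep="NA")

    display = internal.copy()
    for col in display.columns:
        if col.endswith("_pct"):
            display[col] = [
                "NA" if pd.isna(v) else f"{v:.1f}" for v in display[col]
            ]
    widths = {
        col: max(len(col), *(len(str(v)) for v in display[col])) if len(display) else len(col)
        for col in display.columns
    }
    lines = ["  ".join(col.ljust(widths[col]) for col in display.columns)]
    for _, row in display.iterrows():
        lines.append("  ".join(str(row[col]).ljust(widths[col]) for col in display.columns))
    return tsv, "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run clustering (if starting from hits), occupancy building,
    classification and reporting; return the bundle of output paths."""
    config.validate()
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Path] = {}

    with _stage("tree"):
        tree = SpeciesTree.from_file(config.tree)

    with _stage("clustering"):
        if config.blast is not None:
            hits = parse_blast_tab(config.blast, config.evalue_max)
            graph = build_similarity_graph(hits, config.graph_params())
            hgset = mcl_cluster(graph, config.mcl_params())
        else:
            hgset = read_clusters(config.clusters)
        clusters_path = outdir / "clusters.tsv"
        write_clusters(hgset, clusters_path)
        bundle["clusters"] = clusters_path

    with _stage("occupancy"):
        if config.species_map is not None:
            species_of = read_species_map(config.species_map)
        else:
            species_of = species_from_prefix(config.species_delimiter)
        occ = hgset.to_occupancy(species_of)
        extra = sorted(set(occ.columns) - set(tree.leaf_names))
        if extra:
            raise InputError(
                f"species not in tree: {', '.join(extra)} (input {config.blast or config.clusters})"
            )
        # genomes with no clustered proteins are legitimate all-zero columns
        occ = occ.reindex(columns=list(tree.leaf_names), fill_value=0)
        occ_path = outdir / "occupancy.tsv"
        write_occupancy(occ, occ_path)
        bundle["occupancy"] = occ_path

    with _stage("classification"):
        classification = _classify.classify_all(
            tree,
            occ,
            mode=config.mode,
            allowed_absences=config.allowed_absences,
        )
        long_path = outdir / "classification.tsv"
        classification.to_long_frame().to_csv(long_path, sep="\t", index=False)
        bundle["classification"] = long_path

        sets_dir = outdir / "sets"
        sets_dir.mkdir(exist_ok=True)
        for node, cats in classification.items():
            for category in _classify.CATEGORIES:
                hgs = sorted(cats.get(category))
                if not hgs:
                    continue
                path = sets_dir / f"{node}__{category}.txt"
                path.write_text("\n".join(hgs) + "\n")
        bundle["sets"] = sets_dir

    with _stage("report"):
        summary = _classify.summarize(classification)
        summary_path = outdir / "summary.tsv"
        summary.to_csv(
            summary_path, sep="\t", index=False, float_format="%.1f", na_rep="NA"
        )
        bundle["summary"] = summary_path
        node_tsv, node_txt = render_node_table(summary)
        (outdir / "node_table.tsv").write_text(node_tsv)
        (outdir / "node_table.txt").write_text(node_txt)
        bundle["node_table"] = outdir / "node_table.tsv"

        manifest = {"config": asdict(config), "n_hgs": len(hgset), "n_proteins": hgset.n_proteins}
        manifest_path = outdir / "manifest.yaml"
        manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=True))
        bundle["manifest"] = manifest_path

    return bundle
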