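"""End-to-end orchestration: ingest -> ANI -> search -> detect -> summarize.

Stages communicate through files only (each intermediate TSV is re-loadable
and can be supplied precomputed), so a run can be resumed or partially
replaced: `detect` from an existing hits.tsv + ani.tsv gives the same result
as the end-to-end run.  A JSON manifest records the resolved parameters,
input checksums and per-stage counts for reproducibility.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .ani import ANIMatrix, ANIParams, build_ani_matrix
from .detection import (
    DetectionParams,
    assemble_islands,
    cluster_groups,
    filter_hgt_hits,
    promiscuous_genes,
    rank_and_stats,
    species_connections,
    write_detection_tables,
)
from .genome_io import read_genome_dir, read_metadata, write_genes_table
from .homology import HomologyParams, read_hits_tsv, search_all_vs_all, write_hits_tsv
from .summarize import (
    load_annotations,
    per_genome_summary,
    tally_categories,
    write_summary_tables,
)

log = logging.getLogger("hgtscan")


class ValidationError(Exception):
    """Bad configuration or inputs, detected before any compute."""


@dataclass
class RunConfig:
    genome_dir: str
    metadata_path: str
    out_dir: str
    homology: HomologyParams = field(default_factory=HomologyParams)
    ani: ANIParams = field(default_factory=ANIParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    hits_path: str | None = None
    ani_path: str | None = None
    annotations_path: str | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        for label, p in (
            ("genome_dir", self.genome_dir),
            ("metadata_path", self.metadata_path),
            ("hits_path", self.hits_path),
            ("ani_path", self.ani_path),
            ("annotations_path", self.annotations_path),
        ):
            if p is not None and not Path(p).exists():
                raise ValidationError(f"{label} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("genome_dir", "metadata_path", "out_dir", "hits_path",
                    "ani_path", "annotations_path", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        for key, cls_ in (("homology", HomologyParams), ("ani", ANIParams),
                          ("detection", DetectionParams)):
            if key in raw:
                section = dict(raw[key])
                if "mobile_keywords" in section:
                    section["mobile_keywords"] = tuple(section["mobile_keywords"])
                kwargs[key] = cls_(**section)
        missing = {"genome_dir", "metadata_path", "out_dir"} - set(kwargs)
        if missing:
            raise ValidationError(f"run config missing keys: {sorted(missing)}")
        return cls(**kwargs)


def _sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, persist outputs under ``config.out_dir`` and
    return the run manifest (also written as ``manifest.json``)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    manifest: dict = {
        "tool": "hgtscan",
        "version": __version__,
        "started_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
        "parameters": {
            "homology": dataclasses.asdict(config.homology),
            "ani": dataclasses.asdict(config.ani),
            "detection": dataclasses.asdict(config.detection),
        },
        "inputs": {},
        "counts": {},
    }
    stage = "ingest"
    try:
        meta = read_metadata(config.metadata_path)
        genomes = read_genome_dir(config.genome_dir, meta)
        manifest["inputs"]["metadata"] = _sha256(config.metadata_path)
        manifest["counts"]["genomes"] = len(genomes)
        manifest["counts"]["genes"] = sum(len(g.features) for g in genomes)
        write_genes_table(genomes, out / "genes.tsv")
        log.info("stage=ingest genomes=%d genes=%d", len(genomes), manifest["counts"]["genes"])

        stage = "ani"
        ids = [g.genome_id for g in genomes]
        if config.ani_path:
            ani = ANIMatrix.from_tsv(config.ani_path, genome_ids=ids)
        else:
            ani = build_ani_matrix(genomes, config.ani)
        ani.to_tsv(out / "ani.tsv")
        manifest["counts"]["ani_pairs"] = len(ani)
        log.info("stage=ani pairs=%d", len(ani))

        stage = "search"
        if config.hits_path:
            hits = read_hits_tsv(config.hits_path, config.homology)
        else:
            hits = search_all_vs_all(genomes, config.homology)
        write_hits_tsv(hits, out / "hits.tsv")
        manifest["counts"]["hits"] = len(hits)
        log.info("stage=search hits=%d", len(hits))

        stage = "detect"
        edges, candidates = filter_hgt_hits(hits, ani, meta, config.detection)
        islands = assemble_islands(candidates, genomes, config.detection)
        groups = cluster_groups(
            islands, edges, strict=config.detection.min_island_genes <= 1
        )
        groups = rank_and_stats(groups, meta, genomes, config.detection)
        connections = species_connections(edges, meta, config.detection)
        flagged = promiscuous_genes(edges, config.detection)
        write_detection_tables(out, candidates, islands, groups, connections, flagged)
        manifest["counts"].update(
            {
                "retained_edges": len(edges),
                "candidate_genes": len(candidates),
                "islands": len(islands),
                "groups": len(groups),
                "promiscuous_genes": len(flagged),
            }
        )
        log.info(
            "stage=detect candidates=%d islands=%d groups=%d",
            len(candidates), len(islands), len(groups),
        )

        stage = "summarize"
        annotations = (
            load_annotations(config.annotations_path) if config.annotations_path else {}
        )
        tallies = tally_categories(candidates, annotations, "annotated_only")
        rows, footer = per_genome_summary(candidates, islands, groups, genomes)
        write_summary_tables(out, tallies, rows, footer)
        manifest["counts"]["genomes_with_candidates"] = footer.n_with_candidates
        log.info(
            "stage=summarize genomes_with_candidates=%d/%d",
            footer.n_with_candidates, footer.n_genomes,
        )
    except Exception as exc:
        failed_marker.write_text(f"stage={stage}\nerror={exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    # consistency: every candidate sits in exactly one island and one group
    # (islands may drop genes when a min_island_genes filter is active)
    n_island_genes = sum(i.n_genes for i in islands)
    n_group_genes = sum(g.total_genes for g in groups)
    if config.detection.min_island_genes <= 1 and not (
        len(candidates) == n_island_genes == n_group_genes
    ):
        raise RuntimeError(
            "internal count mismatch: "
            f"candidates={len(candidates)} island_genes={n_island_genes} "
            f"group_genes={n_group_genes}"
        )

    manifest["finished_utc"] = time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
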