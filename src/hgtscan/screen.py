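"""Screening marker islands against assembled metagenomes.

Each CDS of a region of interest (e.g. a siderophore-transport island) is
searched against the contigs of every metagenome assembly; a CDS is *present*
in an assembly when some local alignment exceeds the identity threshold
(strictly greater than, default 97%) and covers at least
``min_query_coverage`` of the CDS (default 90% — identity over a trivial
fragment should not count a gene as present).  The per-region result is a
presence/absence matrix with one row per CDS and one column per metagenome.
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import SeqIO

from ._seq import sanitize
from .genome_io import CDSFeature
from .homology import HomologyParams, SeqIndex, align_to_index


@dataclass(frozen=True)
class ScreenParams:
    min_identity: float = 97.0  # strict: present requires identity > threshold
    min_query_coverage: float = 0.90
    kmer_size: int = 21

    def __post_init__(self):
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity must be in (0, 100]")
        if not 0 < self.min_query_coverage <= 1:
            raise ValueError("min_query_coverage must be in (0, 1]")

    def aligner_params(self) -> HomologyParams:
        # search permissively below the call threshold so best_hit_identity
        # is reported even for absent cells
        return HomologyParams(
            min_identity=50.0,
            min_length=self.kmer_size,
            kmer_size=self.kmer_size,
        )


@dataclass(frozen=True)
class ScreenCell:
    cds_id: str
    metagenome_id: str
    present: bool
    best_identity: float  # NaN when no coverage-qualifying alignment exists


@dataclass
class PresenceMatrix:
    region_id: str
    cds_ids: list[str]  # ordered as in the region
    metagenome_ids: list[str]
    cells: dict[tuple[str, str], ScreenCell]

    def cell(self, cds_id: str, metagenome_id: str) -> ScreenCell:
        return self.cells[(cds_id, metagenome_id)]

    def n_present(self, metagenome_id: str) -> int:
        return sum(
            1 for c in self.cds_ids if self.cells[(c, metagenome_id)].present
        )

    @property
    def n_metagenomes_any(self) -> int:
        return sum(1 for m in self.metagenome_ids if self.n_present(m) >= 1)

    @property
    def n_metagenomes_all(self) -> int:
        return sum(
            1 for m in self.metagenome_ids if self.n_present(m) == len(self.cds_ids)
        )


def load_assembly(path: str | os.PathLike) -> dict[str, str]:
    """Contigs of one assembled metagenome as {contig_id: sequence}."""
    path = Path(path)
    contigs = {rec.id: sanitize(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}
    if not contigs:
        raise ValueError(f"empty assembly file: {path}")
    return contigs


def screen_region(
    region: Sequence[CDSFeature],
    assembly: dict[str, str],
    params: ScreenParams | None = None,
    _index: SeqIndex | None = None,
) -> list[tuple[str, bool, float]]:
    """Presence call and best identity for each CDS of a region.

    Returns ``[(cds_id, present, best_identity), ...]`` in region order.
    ``best_identity`` is the identity of the best coverage-qualifying
    alignment on either strand, NaN if none exists.
    """
    params = params or ScreenParams()
    if not assembly:
        raise ValueError("empty assembly")
    index = _index or SeqIndex(assembly, params.kmer_size)
    aln_params = params.aligner_params()
    out = []
    for cds in region:
        best = math.nan
        for alns in align_to_index(cds.nt_sequence, index, aln_params).values():
            for a in alns:
                if a.q_end - a.q_start >= params.min_query_coverage * cds.length:
                    if math.isnan(best) or a.pct_identity > best:
                        best = a.pct_identity
        present = (not math.isnan(best)) and best > params.min_identity
        out.append((cds.gene_id, present, best))
    return out


def build_presence_matrix(
    regions: dict[str, Sequence[CDSFeature]],
    assemblies: dict[str, dict[str, str]],
    params: ScreenParams | None = None,
) -> dict[str, PresenceMatrix]:
    """One complete presence matrix per named region."""
    params = params or ScreenParams()
    if len(set(assemblies)) != len(assemblies):
        raise ValueError("duplicate metagenome ids")
    if not regions or not assemblies:
        raise ValueError("need at least one region and one assembly")
    indexes = {mid: SeqIndex(contigs, params.kmer_size) for mid, contigs in assemblies.items()}
    matrices = {}
    for region_id, cds_list in regions.items():
        cells = {}
        for mid in assemblies:
            for cds_id, present, best in screen_region(
                cds_list, assemblies[mid], params, _index=indexes[mid]
            ):
                cells[(cds_id, mid)] = ScreenCell(cds_id, mid, present, best)
        matrices[region_id] = PresenceMatrix(
            region_id,
            [c.gene_id for c in cds_list],
            sorted(assemblies),
            cells,
        )
    return matrices


def write_screen_tables(
    out_dir: str | os.PathLike, matrices: dict[str, PresenceMatrix]
) -> None:
    """Long-format presence TSV plus a per-region summary TSV."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "screen_presence.tsv"), "w") as fh:
        fh.write("region\tcds_id\tmetagenome\tpresent\tbest_identity\n")
        for region_id in sorted(matrices):
            m = matrices[region_id]
            for cds_id in m.cds_ids:
                for mid in m.metagenome_ids:
                    c = m.cells[(cds_id, mid)]
                    ident = "NA" if math.isnan(c.best_identity) else f"{c.best_identity:.3f}"
                    fh.write(f"{region_id}\t{cds_id}\t{mid}\t{int(c.present)}\t{ident}\n")
    with open(os.path.join(out_dir, "screen_summary.tsv"), "w") as fh:
        fh.write("region\tn_cds\tn_metagenomes\tn_with_any_cds\tn_with_all_cds\n")
        for region_id in sorted(matrices):
            m = matrices[region_id]
            fh.write(
                f"{region_id}\t{len(m.cds_ids)}\t{len(m.metagenome_ids)}\t"
                f"{m.n_metagenomes_any}\t{m.n_metagenomes_all}\n"
            )
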