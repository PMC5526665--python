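"""Core transfer inference: hit filtering, island assembly, group clustering.

A gene becomes a transfer candidate when it has at least one near-identical
hit (from the homology search) to a gene in a genome that is neither the
same species nor a close relative by ANI.  Candidates on one contig are
merged into *islands* when separated by at most ``island_max_gap``
nucleotides (boundary-to-boundary, inclusive); islands across genomes that
share at least one hit-connected gene form *groups* — the connected
components of the island graph and the unit in which transfers are reported.

Mobile elements (transposases etc.) can chain otherwise unrelated islands
into one group.  Following the source pipeline's behaviour this artifact is
reported, not corrected: genes hitting many distinct genomes are flagged as
promiscuous but groups are never auto-split.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .ani import ANIMatrix
from .genome_io import GenomeRecord
from .homology import HomologyHit

DEFAULT_MOBILE_KEYWORDS = (
    "transposase",
    "integrase",
    "conjugal",
    "conjugation",
    "phage",
    "recombinase",
    "mobile element",
    "insertion sequence",
)


@dataclass(frozen=True)
class DetectionParams:
    max_ani: float = 89.0
    island_max_gap: int = 5000
    species_key: str = "species_label"
    min_island_genes: int = 1
    mobile_keywords: tuple[str, ...] = DEFAULT_MOBILE_KEYWORDS
    promiscuous_min_genomes: int = 10

    def __post_init__(self):
        if self.island_max_gap < 0:
            raise ValueError("island_max_gap must be >= 0")
        if not 0 < self.max_ani <= 100:
            raise ValueError("max_ani must be in (0, 100]")
        if self.species_key not in ("species_label", "genome_id"):
            raise ValueError("species_key must be species_label or genome_id")


@dataclass
class CandidateGene:
    genome_id: str
    gene_id: str
    supporting_hits: list[HomologyHit] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, str]:
        return (self.genome_id, self.gene_id)


@dataclass
class Island:
    island_id: str
    genome_id: str
    contig_id: str
    genes: list[CandidateGene]
    span_start: int
    span_end: int
    nt_content: int

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def gene_keys(self) -> set[tuple[str, str]]:
        return {g.key for g in self.genes}


@dataclass
class HGTGroup:
    islands: list[Island]
    group_rank: int = 0
    n_species: int = 0
    total_genes: int = 0
    total_nt: int = 0
    mean_genes_per_species: float = 0.0
    same_phylum: bool | None = None
    single_genus: bool | None = None
    contains_mobile: bool = False

    @property
    def gene_keys(self) -> set[tuple[str, str]]:
        return set().union(*(i.gene_keys for i in self.islands))


def _species_of(genome_id: str, meta: dict[str, dict[str, str]], params: DetectionParams) -> str:
    if params.species_key == "genome_id":
        return genome_id
    row = meta.get(genome_id)
    if row is None:
        raise ValueError(f"genome {genome_id!r} missing from metadata")
    return row.get("species_label") or genome_id


def filter_hgt_hits(
    hits: Sequence[HomologyHit],
    ani: ANIMatrix,
    meta: dict[str, dict[str, str]],
    params: DetectionParams | None = None,
) -> tuple[list[HomologyHit], dict[tuple[str, str], CandidateGene]]:
    """Drop same-species hits and hits between close relatives.

    A hit survives iff (a) the two genomes differ under ``species_key`` and
    (b) the pair's two-way ANI is not above ``max_ani``; a pair with no
    defined ANI is treated as distant and retained.  Returns the retained
    hits and the candidate genes (any gene incident to a retained hit).
    """
    params = params or DetectionParams()
    retained: list[HomologyHit] = []
    candidates: dict[tuple[str, str], CandidateGene] = {}
    for h in hits:
        sp_q = _species_of(h.query_genome, meta, params)
        sp_s = _species_of(h.subject_genome, meta, params)
        if sp_q == sp_s:
            continue
        result = ani.lookup(h.query_genome, h.subject_genome)
        if result is not None and result.defined and result.ani_two_way > params.max_ani:
            continue
        retained.append(h)
        for genome, gene in ((h.query_genome, h.query_gene), (h.subject_genome, h.subject_gene)):
            cand = candidates.setdefault((genome, gene), CandidateGene(genome, gene))
            cand.supporting_hits.append(h)
    return retained, candidates


def assemble_islands(
    candidates: dict[tuple[str, str], CandidateGene],
    genomes: Sequence[GenomeRecord],
    params: DetectionParams | None = None,
) -> list[Island]:
    """Merge candidate genes within ``island_max_gap`` on one contig.

    The gap is measured between the nearest feature boundaries
    (next.start - previous.end) and is inclusive at exactly the threshold;
    non-candidate genes lying inside a gap neither join nor break an island.
    """
    params = params or DetectionParams()
    by_genome = {g.genome_id: g for g in genomes}
    islands: list[Island] = []
    for genome_id in sorted({k[0] for k in candidates}):
        genome = by_genome.get(genome_id)
        if genome is None:
            raise ValueError(f"candidate references unknown genome {genome_id!r}")
        feats = {
            f.gene_id: f for f in genome.features if (genome_id, f.gene_id) in candidates
        }
        missing = {k[1] for k in candidates if k[0] == genome_id} - set(feats)
        if missing:
            raise ValueError(f"candidates not found in genome {genome_id}: {sorted(missing)}")
        by_contig: dict[str, list] = {}
        for f in feats.values():
            by_contig.setdefault(f.contig_id, []).append(f)
        for contig_id in sorted(by_contig):
            run: list = []
            runs: list[list] = []
            prev_end = None
            for f in sorted(by_contig[contig_id], key=lambda f: (f.start, f.end)):
                if prev_end is not None and f.start - prev_end > params.island_max_gap:
                    runs.append(run)
                    run = []
                    prev_end = None
                run.append(f)
                prev_end = f.end if prev_end is None else max(prev_end, f.end)
            if run:
                runs.append(run)
            for serial, members in enumerate(runs, 1):
                if len(members) < params.min_island_genes:
                    continue
                islands.append(
                    Island(
                        island_id=f"{genome_id}:{contig_id}:{serial}",
                        genome_id=genome_id,
                        contig_id=contig_id,
                        genes=[candidates[(genome_id, f.gene_id)] for f in members],
                        span_start=min(f.start for f in members),
                        span_end=max(f.end for f in members),
                        nt_content=sum(f.length for f in members),
                    )
                )
    return islands


def cluster_groups(
    islands: Sequence[Island], edges: Sequence[HomologyHit], strict: bool = True
) -> list[HGTGroup]:
    """Connected components of the island graph under the shared-gene relation.

    Two islands are linked when a retained hit joins a gene of one to a gene
    of the other; components are transitive, so islands with no directly
    shared gene can still co-cluster through intermediates.
    """
    gene_to_island: dict[tuple[str, str], str] = {}
    for isl in islands:
        for key in isl.gene_keys:
            if key in gene_to_island:
                raise ValueError(f"gene {key} belongs to more than one island")
            gene_to_island[key] = isl.island_id
    by_id = {i.island_id: i for i in islands}
    graph = nx.Graph()
    graph.add_nodes_from(by_id)
    for h in edges:
        a = gene_to_island.get((h.query_genome, h.query_gene))
        b = gene_to_island.get((h.subject_genome, h.subject_gene))
        if a is None or b is None:
            if strict:
                raise ValueError(
                    "retained hit endpoint outside every island: "
                    f"{(h.query_genome, h.query_gene)} -> {(h.subject_genome, h.subject_gene)}"
                )
            continue  # endpoint dropped by a min_island_genes filter
        if a != b:
            graph.add_edge(a, b)
    groups = [
        HGTGroup(islands=sorted((by_id[i] for i in comp), key=lambda x: x.island_id))
        for comp in nx.connected_components(graph)
    ]
    return groups


def rank_and_stats(
    groups: Sequence[HGTGroup],
    meta: dict[str, dict[str, str]],
    genomes: Sequence[GenomeRecord] | None = None,
    params: DetectionParams | None = None,
) -> list[HGTGroup]:
    """Fill group statistics and assign deterministic ranks.

    Rank 1 is the group with the most genes; ties break by total nucleotide
    content, then by the lexicographically smallest member genome id.  Taxon
    flags are ``None`` (unknown) when any member genome lacks the label.
    """
    params = params or DetectionParams()
    products: dict[tuple[str, str], str] = {}
    if genomes:
        for g in genomes:
            for f in g.features:
                products[(g.genome_id, f.gene_id)] = f.product
    for grp in groups:
        species = set()
        for isl in grp.islands:
            row = meta.get(isl.genome_id, {})
            species.add(row.get("species_label") or isl.genome_id)
        grp.n_species = len(species)
        grp.total_genes = sum(i.n_genes for i in grp.islands)
        grp.total_nt = sum(i.nt_content for i in grp.islands)
        grp.mean_genes_per_species = grp.total_genes / grp.n_species if grp.n_species else 0.0
        phyla = [meta.get(i.genome_id, {}).get("phylum", "") for i in grp.islands]
        genera = [meta.get(i.genome_id, {}).get("genus", "") for i in grp.islands]
        grp.same_phylum = None if any(not p for p in phyla) else len(set(phyla)) == 1
        grp.single_genus = None if any(not g for g in genera) else len(set(genera)) == 1
        grp.contains_mobile = any(
            kw in products.get(key, "").lower()
            for isl in grp.islands
            for key in sorted(isl.gene_keys)
            for kw in params.mobile_keywords
        )
    ranked = sorted(
        groups,
        key=lambda g: (
            -g.total_genes,
            -g.total_nt,
            min(i.genome_id for i in g.islands),
            min(i.island_id for i in g.islands),
        ),
    )
    for rank, grp in enumerate(ranked, 1):
        grp.group_rank = rank
    return ranked


def species_connections(
    edges: Sequence[HomologyHit],
    meta: dict[str, dict[str, str]],
    params: DetectionParams | None = None,
) -> list[tuple[str, str, int]]:
    """Distinct shared gene pairs per unordered species pair (network table)."""
    params = params or DetectionParams()
    pairs: dict[tuple[str, str], set] = {}
    for h in edges:
        sp = tuple(
            sorted(
                (
                    _species_of(h.query_genome, meta, params),
                    _species_of(h.subject_genome, meta, params),
                )
            )
        )
        gene_pair = frozenset(
            ((h.query_genome, h.query_gene), (h.subject_genome, h.subject_gene))
        )
        pairs.setdefault(sp, set()).add(gene_pair)
    return [(a, b, len(s)) for (a, b), s in sorted(pairs.items())]


def promiscuous_genes(
    edges: Sequence[HomologyHit], params: DetectionParams | None = None
) -> set[tuple[str, str]]:
    """Genes hit by more than ``promiscuous_min_genomes`` distinct genomes —
    the classic signature of a transposon chaining unrelated islands."""
    params = params or DetectionParams()
    partners: dict[tuple[str, str], set[str]] = {}
    for h in edges:
        partners.setdefault((h.query_genome, h.query_gene), set()).add(h.subject_genome)
        partners.setdefault((h.subject_genome, h.subject_gene), set()).add(h.query_genome)
    return {
        gene for gene, pset in partners.items() if len(pset) > params.promiscuous_min_genomes
    }


def write_detection_tables(
    out_dir: str | os.PathLike,
    candidates: dict[tuple[str, str], CandidateGene],
    islands: Sequence[Island],
    groups: Sequence[HGTGroup],
    connections: Sequence[tuple[str, str, int]],
    flagged: set[tuple[str, str]] = frozenset(),
) -> None:
    """Persist candidates/islands/groups/connections as TSV files."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    island_of = {key: isl.island_id for isl in islands for key in isl.gene_keys}
    group_of = {
        isl.island_id: grp.group_rank for grp in groups for isl in grp.islands
    }
    with open(os.path.join(out_dir, "candidates.tsv"), "w") as fh:
        fh.write("genome_id\tgene_id\tisland_id\tgroup_rank\tn_supporting_hits\tpromiscuous\n")
        for key in sorted(candidates):
            cand = candidates[key]
            isl = island_of.get(key, "")
            fh.write(
                f"{key[0]}\t{key[1]}\t{isl}\t{group_of.get(isl, '')}\t"
                f"{len(cand.supporting_hits)}\t{int(key in flagged)}\n"
            )
    with open(os.path.join(out_dir, "islands.tsv"), "w") as fh:
        fh.write("island_id\tgenome_id\tcontig_id\tspan_start\tspan_end\tn_genes\tnt_content\tgroup_rank\n")
        for isl in sorted(islands, key=lambda i: i.island_id):
            fh.write(
                f"{isl.island_id}\t{isl.genome_id}\t{isl.contig_id}\t{isl.span_start}\t"
                f"{isl.span_end}\t{isl.n_genes}\t{isl.nt_content}\t{group_of.get(isl.island_id, '')}\n"
            )
    with open(os.path.join(out_dir, "groups.tsv"), "w") as fh:
        fh.write(
            "group_rank\tn_islands\tn_species\ttotal_genes\ttotal_nt\t"
            "mean_genes_per_species\tsame_phylum\tsingle_genus\tcontains_mobile\n"
        )
        def tri(v: bool | None) -> str:
            return "unknown" if v is None else str(int(v))

        for grp in sorted(groups, key=lambda g: g.group_rank):
            fh.write(
                f"{grp.group_rank}\t{len(grp.islands)}\t{grp.n_species}\t{grp.total_genes}\t"
                f"{grp.total_nt}\t{grp.mean_genes_per_species:.4f}\t{tri(grp.same_phylum)}\t"
                f"{tri(grp.single_genus)}\t{int(grp.contains_mobile)}\n"
            )
    with open(os.path.join(out_dir, "islands.gff3"), "w") as fh:
        fh.write("##gff-version 3\n")
        for isl in sorted(islands, key=lambda i: i.island_id):
            fh.write(
                f"{isl.contig_id}\thgtscan\tgenomic_island\t{isl.span_start + 1}\t"
                f"{isl.span_end}\t.\t.\t.\tID={isl.island_id};genome={isl.genome_id};"
                f"n_genes={isl.n_genes};group_rank={group_of.get(isl.island_id, '')}\n"
            )
    with open(os.path.join(out_dir, "connections.tsv"), "w") as fh:
        fh.write("species_a\tspecies_b\tshared_cds_count\n")
        for a, b, n in connections:
            fh.write(f"{a}\t{b}\t{n}\n")
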