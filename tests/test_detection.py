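"""Hit filtering, island assembly and group clustering rules."""
from __future__ import annotations

import numpy as np
import pytest

from hgtscan.ani import ANIMatrix, ANIResult
from hgtscan.detection import (
    DetectionParams,
    CandidateGene,
    Island,
    assemble_islands,
    cluster_groups,
    filter_hgt_hits,
    rank_and_stats,
    species_connections,
)
from hgtscan.genome_io import CDSFeature, Contig, GenomeRecord
from hgtscan.homology import HomologyHit


def _hit(qg, qgene, sg, sgene, identity=99.5, length=600):
    return HomologyHit(qg, qgene, sg, sgene, identity, length,
                       0, length, 0, length, "+", float(length))


def _ani(a, b, value):
    return ANIResult(a, b, value, value, value, 10, 10, True)


META = {
    "A": {"species_label": "Sp a", "genus": "Ga", "phylum": "Actinomycetota"},
    "B": {"species_label": "Sp b", "genus": "Gb", "phylum": "Actinomycetota"},
    "C": {"species_label": "Sp b", "genus": "Gb", "phylum": "Bacillota"},
    "D": {"species_label": "Sp d", "genus": "Gb", "phylum": "Bacillota"},
}


class TestFilter:
    def test_distant_pair_hit_is_retained(self):
        ani = ANIMatrix([_ani("A", "B", 85.0)])
        edges, cands = filter_hgt_hits([_hit("A", "g1", "B", "g2")], ani, META)
        assert len(edges) == 1
        assert set(cands) == {("A", "g1"), ("B", "g2")}

    def test_same_species_discarded_regardless_of_ani(self):
        ani = ANIMatrix([_ani("B", "C", 50.0)])  # absurdly low, still dropped
        edges, cands = filter_hgt_hits([_hit("B", "g1", "C", "g2")], ani, META)
        assert edges == [] and cands == {}

    @pytest.mark.parametrize("value,kept", [(88.0, True), (89.5, False), (89.0, True)])
    def test_ani_cutoff_is_strictly_greater_than(self, value, kept):
        """Pairs at ~88% ANI pass; the cutoff excludes only ANI > 89."""
        ani = ANIMatrix([_ani("A", "B", value)])
        edges, _ = filter_hgt_hits([_hit("A", "g1", "B", "g2")], ani, META)
        assert bool(edges) == kept

    def test_undefined_ani_treated_as_distant(self):
        ani = ANIMatrix([ANIResult.undefined("A", "B")])
        edges, _ = filter_hgt_hits([_hit("A", "g1", "B", "g2")], ani, META)
        assert len(edges) == 1

    def test_unknown_genome_is_a_validation_error(self):
        with pytest.raises(ValueError, match="ZZ"):
            filter_hgt_hits([_hit("ZZ", "g1", "B", "g2")], ANIMatrix(), META)


def _genome_with_candidates(intervals, contig_len=20_000, genome_id="A",
                            extra=(), n_contigs=1):
    feats = []
    contigs = [Contig(f"c{i + 1}", "A" * contig_len) for i in range(n_contigs)]
    for i, (start, end, *rest) in enumerate(intervals):
        contig = rest[0] if rest else "c1"
        feats.append(CDSFeature(f"g{i + 1}", contig, start, end, "+", "A" * (end - start)))
    for i, (start, end) in enumerate(extra):
        feats.append(CDSFeature(f"x{i + 1}", "c1", start, end, "+", "A" * (end - start)))
    genome = GenomeRecord(genome_id, contigs, feats)
    cands = {
        (genome_id, f"g{i + 1}"): CandidateGene(genome_id, f"g{i + 1}",
                                                [_hit(genome_id, f"g{i + 1}", "B", "y")])
        for i in range(len(intervals))
    }
    return genome, cands


class TestIslands:
    def test_gap_rule_splits_at_more_than_5kb(self):
        genome, cands = _genome_with_candidates([(0, 1000), (3000, 4000), (10_000, 11_000)])
        islands = assemble_islands(cands, [genome])
        sets = sorted(tuple(g.gene_id for g in i.genes) for i in islands)
        assert sets == [("g1", "g2"), ("g3",)]

    @pytest.mark.parametrize("gap,n_islands", [(5000, 1), (5001, 2)])
    def test_boundary_gap_is_inclusive(self, gap, n_islands):
        genome, cands = _genome_with_candidates([(0, 1000), (1000 + gap, 2000 + gap)])
        assert len(assemble_islands(cands, [genome])) == n_islands

    def test_candidates_on_different_contigs_never_merge(self):
        genome, cands = _genome_with_candidates(
            [(0, 1000, "c1"), (1200, 2200, "c2")], n_contigs=2
        )
        islands = assemble_islands(cands, [genome])
        assert len(islands) == 2

    def test_non_candidate_gene_in_gap_does_not_break_island(self):
        genome, cands = _genome_with_candidates(
            [(0, 1000), (4000, 5000)], extra=[(2000, 2500)]
        )
        (island,) = assemble_islands(cands, [genome])
        assert [g.gene_id for g in island.genes] == ["g1", "g2"]

    def test_island_envelope_and_content(self):
        genome, cands = _genome_with_candidates([(100, 700), (1500, 2600)])
        (island,) = assemble_islands(cands, [genome])
        assert (island.span_start, island.span_end) == (100, 2600)
        assert island.nt_content == 600 + 1100
        assert island.nt_content <= island.span_end - island.span_start

    def test_shrinking_gap_never_reduces_island_count(self, community8):
        counts = []
        for gap in (10_000, 5000, 2000, 500, 0):
            params = DetectionParams(island_max_gap=gap)
            counts.append(len(assemble_islands(community8.candidates,
                                               community8.genomes, params)))
        assert counts == sorted(counts)


def _island(island_id, genome, genes):
    cands = [CandidateGene(genome, g) for g in genes]
    return Island(island_id, genome, "c1", cands, 0, 1000, 500)


class TestGroups:
    def test_shared_gene_joins_two_islands(self):
        a = _island("ia", "A", ["g1", "g2"])
        b = _island("ib", "B", ["g3"])
        groups = cluster_groups([a, b], [_hit("A", "g1", "B", "g3")])
        assert len(groups) == 1 and len(groups[0].islands) == 2

    def test_transitive_chaining_without_direct_sharing(self):
        """A-B and B-C edges cluster A with C even with no A-C edge."""
        a, b, c = (_island(f"i{x}", x, [f"{x.lower()}1", f"{x.lower()}2"])
                   for x in "ABC")
        edges = [_hit("A", "a1", "B", "b1"), _hit("B", "b2", "C", "c1")]
        groups = cluster_groups([a, b, c], edges)
        assert len(groups) == 1 and len(groups[0].islands) == 3

    def test_unconnected_islands_stay_separate(self):
        groups = cluster_groups([_island("ia", "A", ["g1"]), _island("ib", "B", ["g2"])], [])
        assert len(groups) == 2

    def test_edge_outside_all_islands_is_an_error(self):
        with pytest.raises(ValueError, match="outside"):
            cluster_groups([_island("ia", "A", ["g1"])], [_hit("A", "g1", "B", "nope")])

    def test_matches_brute_force_transitive_closure(self):
        """Random island graphs: components equal the reflexive-transitive
        closure of the shared-gene relation."""
        rng = np.random.default_rng(55)
        for _ in range(20):
            n = int(rng.integers(2, 30))
            islands = [_island(f"i{k}", f"G{k}", [f"G{k}_g"]) for k in range(n)]
            edges = []
            for _ in range(int(rng.integers(0, n * 2))):
                i, j = rng.integers(0, n, 2)
                if i != j:
                    edges.append(_hit(f"G{i}", f"G{i}_g", f"G{j}", f"G{j}_g"))
            groups = cluster_groups(islands, edges)
            # brute force: repeated pairwise merging until fixpoint
            parts = [{k} for k in range(n)]
            pairs = {(int(h.query_genome[1:]), int(h.subject_genome[1:])) for h in edges}
            changed = True
            while changed:
                changed = False
                for x, y in pairs:
                    px = next(p for p in parts if x in p)
                    py = next(p for p in parts if y in p)
                    if px is not py:
                        parts.remove(py)
                        px |= py
                        changed = True
            ours = {frozenset(int(i.island_id[1:]) for i in g.islands) for g in groups}
            assert ours == {frozenset(p) for p in parts}


class TestRankAndStats:
    def test_mean_genes_per_species(self):
        grp_islands = [
            _island("i1", "A", ["g1", "g2", "g3", "g4"]),
            _island("i2", "B", ["g5", "g6", "g7", "g8"]),
            _island("i3", "D", ["g9", "g10", "g11", "g12"]),
        ]
        groups = cluster_groups(
            grp_islands,
            [_hit("A", "g1", "B", "g5"), _hit("B", "g6", "D", "g10")],
        )
        (ranked,) = rank_and_stats(groups, META)
        assert ranked.n_species == 3
        assert ranked.mean_genes_per_species == 4.0

    def test_rank_ties_break_by_nucleotide_content(self):
        g1 = cluster_groups([_island("i1", "A", ["g1"])], [])[0]
        g2 = cluster_groups([_island("i2", "B", ["g2"])], [])[0]
        g1.islands[0].nt_content = 6000
        g2.islands[0].nt_content = 8000
        ranked = rank_and_stats([g1, g2], META)
        assert ranked[0].total_nt == 8000 and ranked[0].group_rank == 1

    def test_two_phyla_means_not_same_phylum(self):
        groups = cluster_groups(
            [_island("i1", "A", ["g1"]), _island("i2", "C", ["g2"])],
            [_hit("A", "g1", "C", "g2")],
        )
        (ranked,) = rank_and_stats(groups, META)
        assert ranked.same_phylum is False
        assert ranked.single_genus is False

    def test_missing_taxon_labels_report_unknown(self):
        meta = {"A": {"species_label": "Sp a", "genus": "", "phylum": ""},
                "B": META["B"]}
        groups = cluster_groups(
            [_island("i1", "A", ["g1"]), _island("i2", "B", ["g2"])],
            [_hit("A", "g1", "B", "g2")],
        )
        (ranked,) = rank_and_stats(groups, meta)
        assert ranked.same_phylum is None and ranked.single_genus is None

    def test_mobile_keyword_flags_group(self):
        genome = GenomeRecord(
            "A", [Contig("c1", "A" * 2000)],
            [CDSFeature("g1", "c1", 0, 1000, "+", "A" * 1000,
                        product="IS3 family transposase")],
        )
        groups = cluster_groups([_island("i1", "A", ["g1"])], [])
        (ranked,) = rank_and_stats(groups, META, [genome])
        assert ranked.contains_mobile


class TestConnectionsAndConservation:
    def test_connection_counts_distinct_gene_pairs(self):
        edges = [
            _hit("A", "g1", "B", "h1"),
            _hit("B", "h1", "A", "g1"),  # mirror: same gene pair
            _hit("A", "g2", "B", "h2"),
        ]
        table = species_connections(edges, META)
        assert table == [("Sp a", "Sp b", 2)]

    def test_empty_edges_give_empty_table(self):
        assert species_connections([], META) == []

    def test_candidate_partition_is_conserved(self, community8):
        """Every candidate in exactly one island; island and group totals
        both equal the candidate count."""
        keys = [k for isl in community8.islands for k in isl.gene_keys]
        assert len(keys) == len(set(keys)) == len(community8.candidates)
        assert sum(g.total_genes for g in community8.groups) == len(community8.candidates)
        island_ids = [i.island_id for g in community8.groups for i in g.islands]
        assert sorted(island_ids) == sorted(i.island_id for i in community8.islands)

    def test_vertical_relatives_contribute_no_candidates(self, community8):
        """Genes shared only with a close relative (ANI >> cutoff at the
        detectable-identity end) must never appear as candidates."""
        # make relatives nearly identical so their shared genes DO hit,
        # then confirm the ANI filter removes them all
        from hgtscan.ani import build_ani_matrix
        from hgtscan.homology import search_all_vs_all
        from hgtscan.synthetic import SyntheticConfig, generate_community

        config = SyntheticConfig(
            seed=91, n_genomes=3, genome_length=40_000, genes_per_genome=20,
            relative_pairs=(("G1", "G2", 0.002),),
        )
        genomes, _, meta = generate_community(config)
        hits = search_all_vs_all(genomes)
        assert hits, "relatives at 99.8% identity must produce raw hits"
        ani = build_ani_matrix(genomes)
        assert ani.lookup("G1", "G2").ani_two_way > 89.0
        edges, cands = filter_hgt_hits(hits, ani, meta)
        assert cands == {} and edges == []
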