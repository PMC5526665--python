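"""Seed-and-extend aligner vs exhaustive references; tabular hit handling."""
from __future__ import annotations

import shutil
import subprocess

import numpy as np
import pytest

from hgtscan._seq import revcomp
from hgtscan.genome_io import Contig, CDSFeature, GenomeRecord, write_gene_fasta
from hgtscan.homology import (
    HomologyParams,
    align_pair,
    best_alignment,
    parse_tabular_hits,
    read_hits_tsv,
    search_all_vs_all,
    smith_waterman,
    write_hits_tsv,
)
from hgtscan.synthetic import mutate_sequence, random_sequence


def _substituted(seq: str, positions, rng=None) -> str:
    out = list(seq)
    shift = {"A": "C", "C": "G", "G": "T", "T": "A"}
    for p in positions:
        out[p] = shift[out[p]]
    return "".join(out)


def _genome(genome_id: str, genes: dict[str, str], spacer: int = 100) -> GenomeRecord:
    seq_parts, feats, pos = [], [], 0
    for gene_id, gseq in genes.items():
        seq_parts.append("A" * spacer)
        pos += spacer
        seq_parts.append(gseq)
        feats.append(CDSFeature(gene_id, "c1", pos, pos + len(gseq), "+", gseq))
        pos += len(gseq)
    return GenomeRecord(genome_id, [Contig("c1", "".join(seq_parts))], feats)


class TestAlignPair:
    def test_identical_sequences_align_fully(self, rng):
        q = random_sequence(rng, 1000)
        (aln,) = align_pair(q, q)
        assert aln.pct_identity == 100.0
        assert aln.aln_length == 1000
        assert aln.strand == "+"

    def test_reverse_complement_found_on_minus_strand(self, rng):
        q = random_sequence(rng, 800)
        alns = align_pair(q, revcomp(q))
        best = best_alignment(alns)
        assert best.strand == "-"
        assert best.pct_identity == 100.0
        assert best.aln_length == 800

    def test_evenly_spaced_substitutions_defeat_the_thresholds(self, rng):
        """95% identity spread evenly leaves no 99%/500-nt segment."""
        q = random_sequence(rng, 600)
        s = _substituted(q, range(10, 600, 20))  # 30 subs -> 95%
        params = HomologyParams()
        hits = [
            a for a in align_pair(q, s, HomologyParams(min_identity=50))
            if a.aln_length >= params.min_length
            and a.pct_identity >= params.min_identity
        ]
        assert hits == []
        # exhaustive confirmation: the best local alignment is far below 99%
        score, matches, cols = smith_waterman(q, s)
        assert cols > 0 and 100.0 * matches / cols < 99.0
        # and any >=99% stretch must sit between substitutions: < 500 nt
        assert max(np.diff(list(range(10, 600, 20)))) < 500

    @pytest.mark.parametrize("rate", [0.0, 0.01, 0.03])
    def test_matches_smith_waterman_on_diverged_pairs(self, rate):
        """Seeded extension reproduces the exhaustive optimum exactly."""
        rng = np.random.default_rng(97)
        for trial in range(12):
            n = int(rng.integers(300, 2001))
            q = random_sequence(rng, n)
            s = mutate_sequence(q, rate, rng=rng).sequence
            best = best_alignment(align_pair(q, s, HomologyParams(min_identity=50)))
            score, matches, cols = smith_waterman(q, s)
            assert best is not None
            assert best.score == score
            assert (best.n_matches, best.aln_length) == (matches, cols)

    def test_unrelated_sequences_yield_no_alignment(self, rng):
        assert align_pair(random_sequence(rng, 1000), random_sequence(rng, 1000)) == []


class TestSearchAllVsAll:
    def test_shared_gene_reported_in_both_directions(self, rng):
        shared = random_sequence(rng, 1000)
        gx = _genome("X", {"x1": shared, "x2": random_sequence(rng, 700)})
        gy = _genome("Y", {"y1": shared, "y2": random_sequence(rng, 700)})
        hits = search_all_vs_all([gx, gy])
        assert len(hits) == 2
        directions = {(h.query_genome, h.subject_genome) for h in hits}
        assert directions == {("X", "Y"), ("Y", "X")}
        for h in hits:
            assert h.pct_identity == 100.0
            assert h.aln_length == 1000

    @pytest.mark.parametrize("length,expected", [(500, 2), (499, 0)])
    def test_minimum_length_boundary_is_inclusive(self, rng, length, expected):
        shared = random_sequence(rng, length)
        gx = _genome("X", {"x1": shared})
        gy = _genome("Y", {"y1": shared})
        assert len(search_all_vs_all([gx, gy])) == expected

    def test_same_genome_duplicates_are_never_reported(self, rng):
        dup = random_sequence(rng, 900)
        gx = _genome("X", {"x1": dup, "x2": dup})
        gy = _genome("Y", {"y1": random_sequence(rng, 900)})
        assert search_all_vs_all([gx, gy]) == []

    def test_duplicate_gene_identifier_rejected(self, rng):
        g1 = _genome("X", {"a": random_sequence(rng, 600)})
        g2 = GenomeRecord("X", [Contig("c2", "ACGT" * 200)],
                          [CDSFeature("a", "c2", 0, 600, "+", "ACGT" * 150)])
        with pytest.raises(ValueError, match="duplicate"):
            search_all_vs_all([g1, g2])

    def test_raising_thresholds_never_adds_hits(self, community8):
        """Hit-set monotonicity in min_identity and min_length."""
        base = {
            (h.query_genome, h.query_gene, h.subject_genome, h.subject_gene)
            for h in community8.hits
        }
        for params in (
            HomologyParams(min_identity=99.5),
            HomologyParams(min_length=800),
            HomologyParams(min_identity=99.9, min_length=1000),
        ):
            stricter = {
                (h.query_genome, h.query_gene, h.subject_genome, h.subject_gene)
                for h in search_all_vs_all(community8.genomes, params)
            }
            assert stricter <= base

    def test_hit_table_is_deterministic(self, rng):
        shared = random_sequence(rng, 1200)
        gx = _genome("X", {"x1": shared, "x2": random_sequence(rng, 600)})
        gy = _genome("Y", {"y1": shared})
        assert search_all_vs_all([gx, gy]) == search_all_vs_all([gx, gy])


class TestTabularHits:
    ID_MAP = {
        "X|g1": ("X", "g1"), "Y|g2": ("Y", "g2"), "X|g3": ("X", "g3"),
    }

    def test_qualifying_row_is_retained_and_converted(self):
        rows = ["X|g1\tY|g2\t99.31\t642\t4\t0\t1\t642\t10\t651\t0.0\t1180"]
        hits, dropped = parse_tabular_hits(rows, self.ID_MAP)
        (h,) = hits
        assert dropped == 0
        assert (h.q_start, h.q_end) == (0, 642)
        assert (h.s_start, h.s_end) == (9, 651)
        assert h.strand == "+"

    def test_identity_below_threshold_dropped(self):
        rows = ["X|g1\tY|g2\t98.9\t2000\t22\t0\t1\t2000\t1\t2000\t0.0\t3000"]
        hits, _ = parse_tabular_hits(rows, self.ID_MAP)
        assert hits == []

    def test_same_genome_row_dropped_with_count(self):
        rows = ["X|g1\tX|g3\t99.9\t600\t0\t0\t1\t600\t1\t600\t0.0\t1100"]
        hits, dropped = parse_tabular_hits(rows, self.ID_MAP)
        assert hits == [] and dropped == 1

    def test_malformed_row_names_line_number(self):
        rows = ["X|g1\tY|g2\t99.5\t600"]
        with pytest.raises(ValueError, match="line 1"):
            parse_tabular_hits(rows, self.ID_MAP)

    def test_unresolvable_id_is_named(self):
        rows = ["Z|zz\tY|g2\t99.5\t600\t3\t0\t1\t600\t1\t600\t0.0\t1100"]
        with pytest.raises(ValueError, match="Z|zz"):
            parse_tabular_hits(rows, self.ID_MAP)

    def test_round_trip_through_tsv(self, rng, tmp_path):
        shared = random_sequence(rng, 1000)
        hits = search_all_vs_all([_genome("X", {"x1": shared}), _genome("Y", {"y1": shared})])
        path = tmp_path / "hits.tsv"
        write_hits_tsv(hits, path)
        back = read_hits_tsv(path)
        assert [
            (h.query_genome, h.query_gene, h.subject_genome, h.subject_gene,
             h.aln_length, h.q_start, h.q_end, h.s_start, h.s_end, h.strand)
            for h in back
        ] == [
            (h.query_genome, h.query_gene, h.subject_genome, h.subject_gene,
             h.aln_length, h.q_start, h.q_end, h.s_start, h.s_end, h.strand)
            for h in hits
        ]


@pytest.mark.skipif(shutil.which("blastn") is None, reason="blastn not on PATH")
def test_agrees_with_blastn_on_retained_gene_pairs(tmp_path, rng):
    """Independent cross-check: same qualifying gene pairs as BLAST+."""
    shared1 = random_sequence(rng, 1000)
    base2 = random_sequence(rng, 800)
    gx = _genome("X", {"x1": shared1, "x2": random_sequence(rng, 700),
                       "x3": base2})
    gy = _genome("Y", {"y1": shared1,
                       "y3": mutate_sequence(base2, 0.005, rng=rng).sequence,
                       "y2": random_sequence(rng, 700)})
    ours = {
        frozenset([(h.query_genome, h.query_gene), (h.subject_genome, h.subject_gene)])
        for h in search_all_vs_all([gx, gy])
    }
    qf, sf = tmp_path / "x.fasta", tmp_path / "y.fasta"
    write_gene_fasta(gx, qf)
    write_gene_fasta(gy, sf)
    db = tmp_path / "db"
    subprocess.run(
        ["makeblastdb", "-in", str(sf), "-dbtype", "nucl", "-out", str(db)],
        check=True, capture_output=True,
    )
    out = subprocess.run(
        ["blastn", "-query", str(qf), "-db", str(db), "-outfmt", "6"],
        check=True, capture_output=True, text=True,
    )
    hits, _ = parse_tabular_hits(
        out.stdout.splitlines(), lambda h: tuple(h.split("|", 1))
    )
    theirs = {
        frozenset([(h.query_genome, h.query_gene), (h.subject_genome, h.subject_gene)])
        for h in hits
    }
    assert ours == theirs
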