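"""Fragment-based average nucleotide identity (ANI) between genome pairs.

ANI is the vertical-inheritance control of the transfer detector: gene hits
between genomes whose ANI exceeds the cutoff (default 89%) are attributed to
shared ancestry rather than transfer and discarded.  The estimator follows
the classic fragment scheme: each genome is cut into non-overlapping 1000-nt
tiles, every tile of A is aligned against the whole of B, and a tile
qualifies when its best hit reaches >=70% identity over >=70% of the tile.
One-way ANI is the mean identity of qualifying best hits; the two-way value
is the mean of the two directions.  A direction with fewer than
``min_fragments`` qualifying tiles leaves the pair *undefined* — downstream
an undefined ANI passes the filter (unrelated genomes are never mistaken for
close relatives).
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Sequence

from .genome_io import GenomeRecord
from .homology import HomologyParams, SeqIndex, align_to_index, best_alignment


@dataclass(frozen=True)
class ANIParams:
    fragment_length: int = 1000
    fragment_step: int = 1000
    best_hit_min_identity: float = 70.0
    best_hit_min_coverage: float = 0.70
    min_fragments: int = 5
    # an ANI estimate is only meaningful when a reasonable share of the
    # query's fragments aligned at all: genomes that merely exchanged one
    # island align over a few tiles at ~100% identity, which must not make
    # them look like close relatives (cf. the aligned-fraction convention
    # of whole-genome ANI tools)
    min_fragment_fraction: float = 0.2
    kmer_size: int = 15

    def __post_init__(self):
        if not 0 < self.best_hit_min_coverage <= 1:
            raise ValueError("best_hit_min_coverage must be in (0, 1]")
        if self.fragment_step <= 0 or self.fragment_length <= 0:
            raise ValueError("fragment length/step must be positive")

    def aligner_params(self) -> HomologyParams:
        # permissive search: qualification is decided here, not by the aligner
        return HomologyParams(
            min_identity=self.best_hit_min_identity,
            min_length=self.kmer_size,
            kmer_size=self.kmer_size,
        )


@dataclass(frozen=True)
class ANIResult:
    genome_a: str
    genome_b: str
    ani_ab: float
    ani_ba: float
    ani_two_way: float
    n_fragments_used_ab: int
    n_fragments_used_ba: int
    defined: bool

    @staticmethod
    def undefined(a: str, b: str, n_ab: int = 0, n_ba: int = 0) -> "ANIResult":
        return ANIResult(a, b, math.nan, math.nan, math.nan, n_ab, n_ba, False)


def fragment_genome(genome: GenomeRecord, params: ANIParams | None = None):
    """Tile each contig; a terminal fragment shorter than ``fragment_length``
    is kept only if it is at least half a fragment long."""
    params = params or ANIParams()
    L, step = params.fragment_length, params.fragment_step
    out = []
    for contig in genome.contigs:
        for start in range(0, contig.length, step):
            frag = contig.sequence[start : start + L]
            if len(frag) == L or len(frag) * 2 >= L:
                out.append((contig.contig_id, start, frag))
    return out


def _genome_index(genome: GenomeRecord, params: ANIParams) -> SeqIndex:
    return SeqIndex(
        {c.contig_id: c.sequence for c in genome.contigs}, params.kmer_size
    )


def _one_way(
    query: GenomeRecord,
    target_index: SeqIndex,
    params: ANIParams,
) -> tuple[float, int, int]:
    aln_params = params.aligner_params()
    identities = []
    fragments = fragment_genome(query, params)
    for _, _, frag in fragments:
        alns = [a for per in align_to_index(frag, target_index, aln_params).values() for a in per]
        best = best_alignment(alns)
        if best is None:
            continue
        if (
            best.pct_identity >= params.best_hit_min_identity
            and best.aln_length >= params.best_hit_min_coverage * len(frag)
        ):
            identities.append(best.pct_identity)
    if not identities:
        return math.nan, 0, len(fragments)
    return sum(identities) / len(identities), len(identities), len(fragments)


def compute_ani(
    genome_a: GenomeRecord,
    genome_b: GenomeRecord,
    params: ANIParams | None = None,
    _index_a: SeqIndex | None = None,
    _index_b: SeqIndex | None = None,
) -> ANIResult:
    """Two-way fragment ANI between a pair of genomes."""
    params = params or ANIParams()
    index_a = _index_a or _genome_index(genome_a, params)
    index_b = _index_b or _genome_index(genome_b, params)
    ani_ab, n_ab, total_ab = _one_way(genome_a, index_b, params)
    ani_ba, n_ba, total_ba = _one_way(genome_b, index_a, params)

    def ok(n: int, total: int) -> bool:
        return n >= params.min_fragments and n >= params.min_fragment_fraction * total

    if not (ok(n_ab, total_ab) and ok(n_ba, total_ba)):
        return ANIResult.undefined(genome_a.genome_id, genome_b.genome_id, n_ab, n_ba)
    return ANIResult(
        genome_a.genome_id,
        genome_b.genome_id,
        ani_ab,
        ani_ba,
        (ani_ab + ani_ba) / 2.0,
        n_ab,
        n_ba,
        True,
    )


class ANIMatrix:
    """Symmetric lookup of :class:`ANIResult` per unordered genome pair."""

    def __init__(self, results: Sequence[ANIResult] = ()):
        self._by_pair: dict[frozenset, ANIResult] = {}
        for r in results:
            self.add(r)

    def add(self, result: ANIResult) -> None:
        self._by_pair[frozenset((result.genome_a, result.genome_b))] = result

    def lookup(self, a: str, b: str) -> ANIResult | None:
        return self._by_pair.get(frozenset((a, b)))

    def __len__(self) -> int:
        return len(self._by_pair)

    def __iter__(self):
        return iter(sorted(self._by_pair.values(), key=lambda r: (r.genome_a, r.genome_b)))

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(
                "genome_a\tgenome_b\tani_ab\tani_ba\tani_two_way\t"
                "n_frag_ab\tn_frag_ba\tdefined\n"
            )
            for r in self:
                def fmt(x: float) -> str:
                    return "NA" if math.isnan(x) else f"{x:.4f}"

                fh.write(
                    f"{r.genome_a}\t{r.genome_b}\t{fmt(r.ani_ab)}\t{fmt(r.ani_ba)}\t"
                    f"{fmt(r.ani_two_way)}\t{r.n_fragments_used_ab}\t"
                    f"{r.n_fragments_used_ba}\t{int(r.defined)}\n"
                )

    @classmethod
    def from_tsv(
        cls, path: str | os.PathLike, genome_ids: Sequence[str] | None = None
    ) -> "ANIMatrix":
        matrix = cls()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                if not line.strip():
                    continue
                row = dict(zip(header, line.rstrip("\n").split("\t")))

                def num(key: str) -> float:
                    return math.nan if row[key] == "NA" else float(row[key])

                matrix.add(
                    ANIResult(
                        row["genome_a"],
                        row["genome_b"],
                        num("ani_ab"),
                        num("ani_ba"),
                        num("ani_two_way"),
                        int(row["n_frag_ab"]),
                        int(row["n_frag_ba"]),
                        bool(int(row["defined"])),
                    )
                )
        if genome_ids is not None:
            missing = [
                (a, b)
                for i, a in enumerate(genome_ids)
                for b in genome_ids[i + 1 :]
                if matrix.lookup(a, b) is None
            ]
            if missing:
                raise ValueError(f"ANI matrix {path} is missing pairs: {missing}")
        return matrix


def build_ani_matrix(
    genomes: Sequence[GenomeRecord], params: ANIParams | None = None
) -> ANIMatrix:
    """All unordered pairs; per-genome k-mer indexes are built once."""
    params = params or ANIParams()
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    indexes = {g.genome_id: _genome_index(g, params) for g in genomes}
    matrix = ANIMatrix()
    for i, a in enumerate(genomes):
        for b in genomes[i + 1 :]:
            matrix.add(
                compute_ani(
                    a, b, params,
                    _index_a=indexes[a.genome_id],
                    _index_b=indexes[b.genome_id],
                )
            )
    return matrix
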