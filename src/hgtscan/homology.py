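"""Pairwise nucleotide homology search between protein-coding genes.

The search that feeds transfer detection needs near-identical hits only
(by default >=99% identity over >=500 nt), so a seed-and-extend strategy with
long exact k-mer seeds (k=31) is sufficient: any alignment at those
thresholds contains many intact 31-mers.  Seeds are extended with banded
affine-gap X-drop dynamic programming; overlapping alignments are collapsed
keeping the highest-scoring one.  Percent identity counts gap columns in the
denominator (a gap column is a non-match), matching the convention of the
12-column tabular hit format this module also reads and writes.

:func:`smith_waterman` is a full quadratic-time local aligner kept as an
exhaustive reference; it is deliberately independent of the seeded path.
"""
from __future__ import annotations

import sys
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from ._kernels import extend_kernel, sw_kernel
from ._seq import encode, revcomp
from .genome_io import GenomeRecord

# Cap on extensions attempted per (query, target, strand); seeds beyond this
# are only reached for pathologically repetitive inputs.
_MAX_EXTENSIONS = 200


@dataclass(frozen=True)
class HomologyParams:
    """Thresholds and scoring for the gene-vs-gene search."""

    min_identity: float = 99.0
    min_length: int = 500
    kmer_size: int = 31
    xdrop: int = 20
    match_score: int = 1
    mismatch_score: int = -2
    gap_open: int = -4
    gap_extend: int = -2
    band: int = 16
    search_both_strands: bool = True

    def __post_init__(self):
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity must be in (0, 100]")
        if not self.min_length >= self.kmer_size >= 8:
            raise ValueError("require min_length >= kmer_size >= 8")


@dataclass(frozen=True)
class LocalAlignment:
    """One local alignment; coordinates are 0-based half-open on the forward
    strands of both sequences.  For strand '-' the aligned text is the query
    against the reverse complement of the subject interval."""

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    n_matches: int
    aln_length: int
    score: int

    @property
    def pct_identity(self) -> float:
        return 100.0 * self.n_matches / self.aln_length


@dataclass(frozen=True)
class HomologyHit:
    query_genome: str
    query_gene: str
    subject_genome: str
    subject_gene: str
    pct_identity: float
    aln_length: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    score: float

    def __post_init__(self):
        if self.query_genome == self.subject_genome:
            raise ValueError("self-genome hits are never emitted")
        if self.aln_length <= 0:
            raise ValueError("aln_length must be positive")

    def reversed(self) -> "HomologyHit":
        return HomologyHit(
            self.subject_genome,
            self.subject_gene,
            self.query_genome,
            self.query_gene,
            self.pct_identity,
            self.aln_length,
            self.s_start,
            self.s_end,
            self.q_start,
            self.q_end,
            self.strand,
            self.score,
        )


class SeqIndex:
    """Exact k-mer index over a set of named target sequences."""

    def __init__(self, targets: dict[str, str], k: int):
        self.k = k
        self.encoded = {tid: encode(s) for tid, s in targets.items()}
        self.lengths = {tid: len(s) for tid, s in targets.items()}
        self._index: dict[str, list[tuple[str, int]]] = {}
        for tid, seq in targets.items():
            for pos in range(0, len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((tid, pos))

    def seeds(self, query: str, exclude: Callable[[str], bool] | None = None):
        """Yield (target_id, query_pos, target_pos) for shared k-mers."""
        k = self.k
        idx = self._index
        for qpos in range(0, len(query) - k + 1):
            hits = idx.get(query[qpos : qpos + k])
            if not hits:
                continue
            for tid, tpos in hits:
                if exclude is not None and exclude(tid):
                    continue
                yield tid, qpos, tpos


def _extend_seed(enc_q, enc_t, qpos, tpos, params: HomologyParams):
    sc = (params.match_score, params.mismatch_score, params.gap_open, params.gap_extend)
    sL = iL = jL = mL = cL = 0
    if qpos > 0 and tpos > 0:
        ql = np.ascontiguousarray(enc_q[:qpos][::-1])
        tl = np.ascontiguousarray(enc_t[:tpos][::-1])
        sL, iL, jL, mL, cL = extend_kernel(ql, tl, *sc, params.band, params.xdrop)
    qr = np.ascontiguousarray(enc_q[qpos:])
    tr = np.ascontiguousarray(enc_t[tpos:])
    sR, iR, jR, mR, cR = extend_kernel(qr, tr, *sc, params.band, params.xdrop)
    return (
        sL + sR,
        qpos - iL,
        qpos + iR,
        tpos - jL,
        tpos + jR,
        mL + mR,
        cL + cR,
    )


def _covered(alignments, qpos, tpos, band):
    for a in alignments:
        if (
            a.q_start <= qpos < a.q_end
            and a.s_start <= tpos < a.s_end
            and abs((qpos - tpos) - (a.q_start - a.s_start)) <= band
        ):
            return True
    return False


def _align_one_strand(query: str, index: SeqIndex, params: HomologyParams, strand: str, exclude):
    """Alignments of (possibly reverse-complemented) query against the index."""
    q = revcomp(query) if strand == "-" else query
    enc_q = encode(q)
    nq = len(q)
    per_target: dict[str, list[LocalAlignment]] = {}
    n_ext: dict[str, int] = {}
    for tid, qpos, tpos in index.seeds(q, exclude):
        found = per_target.setdefault(tid, [])
        if n_ext.get(tid, 0) >= _MAX_EXTENSIONS:
            continue
        if _covered(found, qpos, tpos, params.band):
            continue
        n_ext[tid] = n_ext.get(tid, 0) + 1
        score, q0, q1, t0, t1, m, c = _extend_seed(
            enc_q, index.encoded[tid], qpos, tpos, params
        )
        if c == 0:
            continue
        found.append(LocalAlignment(q0, q1, t0, t1, "+", m, c, score))
    out: dict[str, list[LocalAlignment]] = {}
    for tid, alns in per_target.items():
        mapped = []
        for a in alns:
            if strand == "-":
                # map coordinates of the reverse-complemented query back
                mapped.append(
                    LocalAlignment(
                        nq - a.q_end, nq - a.q_start, a.s_start, a.s_end,
                        "-", a.n_matches, a.aln_length, a.score,
                    )
                )
            else:
                mapped.append(a)
        out[tid] = mapped
    return out


def _dedupe(alignments: list[LocalAlignment]) -> list[LocalAlignment]:
    """Keep highest-scoring alignments, dropping ones overlapping a kept one
    in both query and subject intervals."""
    kept: list[LocalAlignment] = []
    for a in sorted(alignments, key=lambda a: (-a.score, a.q_start, a.s_start)):
        clash = any(
            a.q_start < k.q_end and k.q_start < a.q_end
            and a.s_start < k.s_end and k.s_start < a.s_end
            for k in kept
        )
        if not clash:
            kept.append(a)
    return kept


def align_to_index(
    query: str,
    index: SeqIndex,
    params: HomologyParams,
    exclude: Callable[[str], bool] | None = None,
) -> dict[str, list[LocalAlignment]]:
    """Best local alignments of ``query`` against every indexed target."""
    if not query:
        raise ValueError("empty query sequence")
    merged: dict[str, list[LocalAlignment]] = {}
    strands = ["+", "-"] if params.search_both_strands else ["+"]
    for strand in strands:
        for tid, alns in _align_one_strand(query, index, params, strand, exclude).items():
            merged.setdefault(tid, []).extend(alns)
    return {tid: _dedupe(alns) for tid, alns in merged.items() if alns}


def align_pair(query: str, subject: str, params: HomologyParams | None = None) -> list[LocalAlignment]:
    """All merged local alignments between two sequences (both strands)."""
    params = params or HomologyParams()
    if not query or not subject:
        raise ValueError("sequences must be non-empty")
    index = SeqIndex({"subject": subject}, params.kmer_size)
    return align_to_index(query, index, params).get("subject", [])


def best_alignment(alignments: Sequence[LocalAlignment]) -> LocalAlignment | None:
    """Single best alignment: highest score, ties by q_start then s_start."""
    if not alignments:
        return None
    return min(alignments, key=lambda a: (-a.score, a.q_start, a.s_start))


def smith_waterman(query: str, subject: str, params: HomologyParams | None = None):
    """Exhaustive affine-gap local alignment (reference implementation).

    Returns ``(score, n_matches, aln_length)`` of the best local alignment,
    or ``(0, 0, 0)`` if nothing scores positively.  Quadratic time; intended
    for validation on small inputs, not for production search.
    """
    params = params or HomologyParams()
    score, _, _, m, c = sw_kernel(
        encode(query),
        encode(subject),
        params.match_score,
        params.mismatch_score,
        params.gap_open,
        params.gap_extend,
    )
    return int(score), int(m), int(c)


def _passes(aln: LocalAlignment, params: HomologyParams) -> bool:
    return (
        aln.aln_length >= params.min_length
        and aln.pct_identity >= params.min_identity - 1e-9
    )


def search_all_vs_all(
    genomes: Sequence[GenomeRecord], params: HomologyParams | None = None
) -> list[HomologyHit]:
    """All qualifying gene-vs-gene hits between distinct genomes.

    Exactly one (best-scoring) alignment is kept per gene pair; each retained
    pair is reported in both directions.  Output order is stable:
    (query_genome, query_gene, subject_genome, subject_gene).
    """
    params = params or HomologyParams()
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    genes: list[tuple[str, str, str]] = []
    seen = set()
    for g in genomes:
        for f in g.features:
            key = (g.genome_id, f.gene_id)
            if key in seen:
                raise ValueError(f"duplicate gene identifier {key}")
            seen.add(key)
            genes.append((g.genome_id, f.gene_id, f.nt_sequence))

    targets = {f"{i}": seq for i, (_, _, seq) in enumerate(genes)}
    index = SeqIndex(targets, params.kmer_size)
    hits: list[HomologyHit] = []
    for qi, (q_genome, q_gene, q_seq) in enumerate(genes):

        def exclude(tid: str, qi=qi, q_genome=q_genome) -> bool:
            ti = int(tid)
            # each unordered pair aligned once, mirrored afterwards
            return ti <= qi or genes[ti][0] == q_genome

        for tid, alns in align_to_index(q_seq, index, params, exclude).items():
            best = best_alignment([a for a in alns if _passes(a, params)])
            if best is None:
                continue
            s_genome, s_gene, _ = genes[int(tid)]
            fwd = HomologyHit(
                q_genome, q_gene, s_genome, s_gene,
                best.pct_identity, best.aln_length,
                best.q_start, best.q_end, best.s_start, best.s_end,
                best.strand, float(best.score),
            )
            hits.append(fwd)
            hits.append(fwd.reversed())
    hits.sort(key=lambda h: (h.query_genome, h.query_gene, h.subject_genome, h.subject_gene))
    return hits


def parse_tabular_hits(
    lines: Iterable[str],
    id_map: Callable[[str], tuple[str, str]] | dict[str, tuple[str, str]],
    params: HomologyParams | None = None,
) -> tuple[list[HomologyHit], int]:
    """Ingest 12-column tabular hits (qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore).

    1-based inclusive coordinates are converted to 0-based half-open; rows
    whose two identifiers resolve to the same genome are dropped and counted
    (second return value); identity/length thresholds are applied exactly as
    in the internal search.
    """
    params = params or HomologyParams()
    if isinstance(id_map, dict):
        mapping = id_map
        resolve = lambda h: mapping[h]  # noqa: E731
    else:
        resolve = id_map
    hits: list[HomologyHit] = []
    n_same_genome = 0
    for lineno, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 12:
            raise ValueError(f"line {lineno}: expected 12 columns, got {len(cols)}")
        try:
            qseqid, sseqid = cols[0], cols[1]
            pident = float(cols[2])
            length = int(cols[3])
            qstart, qend = int(cols[6]), int(cols[7])
            sstart, send = int(cols[8]), int(cols[9])
            bitscore = float(cols[11])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: malformed row ({exc})") from None
        try:
            q_genome, q_gene = resolve(qseqid)
            s_genome, s_gene = resolve(sseqid)
        except KeyError:
            bad = qseqid if _unresolvable(resolve, qseqid) else sseqid
            raise ValueError(f"line {lineno}: unresolvable identifier {bad!r}") from None
        if q_genome == s_genome:
            n_same_genome += 1
            continue
        if pident < params.min_identity - 1e-9 or length < params.min_length:
            continue
        if sstart <= send:
            strand, s0, s1 = "+", sstart - 1, send
        else:
            strand, s0, s1 = "-", send - 1, sstart
        hits.append(
            HomologyHit(
                q_genome, q_gene, s_genome, s_gene, pident, length,
                qstart - 1, qend, s0, s1, strand, bitscore,
            )
        )
    return hits, n_same_genome


def _unresolvable(resolve, header: str) -> bool:
    try:
        resolve(header)
        return False
    except KeyError:
        return True


def write_hits_tsv(hits: Sequence[HomologyHit], path) -> None:
    """Write hits in the 12-column tabular format, headers ``genome|gene``."""
    with open(path, "w") as fh:
        for h in hits:
            mismatch = round(h.aln_length * (100.0 - h.pct_identity) / 100.0)
            if h.strand == "+":
                sstart, send = h.s_start + 1, h.s_end
            else:
                sstart, send = h.s_end, h.s_start + 1
            fh.write(
                f"{h.query_genome}|{h.query_gene}\t{h.subject_genome}|{h.subject_gene}\t"
                f"{h.pct_identity:.3f}\t{h.aln_length}\t{mismatch}\t0\t"
                f"{h.q_start + 1}\t{h.q_end}\t{sstart}\t{send}\t0.0\t{h.score:.1f}\n"
            )


def read_hits_tsv(path, params: HomologyParams | None = None) -> list[HomologyHit]:
    """Read hits written by :func:`write_hits_tsv` (``genome|gene`` headers)."""

    def resolve(header: str) -> tuple[str, str]:
        if "|" not in header:
            raise KeyError(header)
        genome, gene = header.split("|", 1)
        return genome, gene

    with open(path) as fh:
        hits, dropped = parse_tabular_hits(fh, resolve, params)
    if dropped:
        print(f"warning: dropped {dropped} same-genome rows from {path}", file=sys.stderr)
    return hits
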