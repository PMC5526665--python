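"""Seeded synthetic bacterial communities with planted gene transfers.

The generator emulates the inputs the detector was built for: a set of
annotated genomes containing (a) background genes unique to each genome,
(b) vertically related genome pairs derived from a shared ancestor at a
controlled substitution rate, and (c) multi-gene islands copied from a donor
into distant recipients at a controlled per-site divergence.  Optional
transposon confounders — one short element copied verbatim next to islands
of different origins — reproduce the documented failure mode where a shared
mobile gene chains unrelated islands into one group.

Divergence is substitution-only by default so identity and ANI have
closed-form (Hamming) expectations; short indels can be switched on.  Genes
are plain sequence intervals, not ORFs: nothing downstream inspects codon
structure.  Ground truth records every planted gene, whether it is
*detectable* at the detection thresholds (realized identity and length),
the island partition implied by the proximity rule, and the expected group
partition (one group per island spec, one per transposon element).
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._seq import encode
from .genome_io import CDSFeature, Contig, GenomeRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_ISLAND_PRODUCTS = (
    "iron-siderophore ABC transporter substrate-binding protein",
    "iron-siderophore ABC transporter permease",
    "siderophore ABC transporter ATP-binding protein",
    "TonB-dependent siderophore receptor",
    "lactate permease",
    "lactate dehydrogenase",
)
_TRANSPOSON_PRODUCT = "IS110 family transposase"
_BACKGROUND_PRODUCT = "hypothetical protein"


@dataclass(frozen=True)
class IslandSpec:
    spec_id: str
    donor_genome: str
    recipient_genomes: tuple[str, ...]
    n_genes: int
    gene_lengths: tuple[int, ...] | None = None  # default 800 nt each
    intergene_gaps: tuple[int, ...] | None = None  # default 200 nt
    per_site_divergence: float = 0.0

    def resolved_lengths(self) -> tuple[int, ...]:
        if self.gene_lengths is not None:
            if len(self.gene_lengths) != self.n_genes:
                raise ValueError(f"{self.spec_id}: need {self.n_genes} gene lengths")
            return tuple(self.gene_lengths)
        return (800,) * self.n_genes

    def resolved_gaps(self) -> tuple[int, ...]:
        if self.intergene_gaps is not None:
            if len(self.intergene_gaps) != self.n_genes - 1:
                raise ValueError(f"{self.spec_id}: need {self.n_genes - 1} gaps")
            return tuple(self.intergene_gaps)
        return (200,) * max(0, self.n_genes - 1)

    @property
    def cassette_length(self) -> int:
        return sum(self.resolved_lengths()) + sum(self.resolved_gaps())

    @property
    def members(self) -> tuple[str, ...]:
        return (self.donor_genome, *self.recipient_genomes)


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int
    n_genomes: int = 8
    genome_length: int = 100_000
    gc_content: float = 0.5
    genes_per_genome: int = 60
    gene_length_range: tuple[int, int] = (600, 1500)
    relative_pairs: tuple[tuple[str, str, float], ...] = ()
    planted_islands: tuple[IslandSpec, ...] = ()
    confounder_transposons: int = 0
    transposon_length: int = 1200
    transposon_scatter: int = 4  # extra verbatim copies per element, spread over other genomes

    def __post_init__(self):
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        for _, _, rate in self.relative_pairs:
            if not 0 <= rate < 1:
                raise ValueError("relative-pair rates must be in [0, 1)")

    def genome_ids(self) -> list[str]:
        return [f"G{i + 1}" for i in range(self.n_genomes)]


@dataclass(frozen=True)
class PlantedGene:
    genome_id: str
    gene_id: str
    spec_id: str
    realized_identity: float  # vs the donor copy, percent
    detectable: bool


@dataclass
class TruthSet:
    planted: list[PlantedGene]
    expected_islands: dict[str, list[list[str]]]  # genome -> gene-id runs
    expected_groups: dict[str, list[list[str]]]  # spec -> [genome, gene] keys
    relative_expected_ani: list[tuple[str, str, float]]
    transposon_genes: list[tuple[str, str]]
    detect_min_identity: float = 99.0
    detect_min_length: int = 500

    def planted_keys(self) -> set[tuple[str, str]]:
        return {(p.genome_id, p.gene_id) for p in self.planted}

    def detectable_keys(self) -> set[tuple[str, str]]:
        return {(p.genome_id, p.gene_id) for p in self.planted if p.detectable}

    def spec_of(self) -> dict[tuple[str, str], str]:
        return {(p.genome_id, p.gene_id): p.spec_id for p in self.planted}

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "planted": [
                [p.genome_id, p.gene_id, p.spec_id, p.realized_identity, p.detectable]
                for p in self.planted
            ],
            "expected_islands": self.expected_islands,
            "expected_groups": self.expected_groups,
            "relative_expected_ani": [list(t) for t in self.relative_expected_ani],
            "transposon_genes": [list(t) for t in self.transposon_genes],
            "detect_min_identity": self.detect_min_identity,
            "detect_min_length": self.detect_min_length,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            planted=[PlantedGene(*row) for row in d["planted"]],
            expected_islands=d["expected_islands"],
            expected_groups=d["expected_groups"],
            relative_expected_ani=[tuple(t) for t in d["relative_expected_ani"]],
            transposon_genes=[tuple(t) for t in d["transposon_genes"]],
            detect_min_identity=d["detect_min_identity"],
            detect_min_length=d["detect_min_length"],
        )


@dataclass(frozen=True)
class MutationResult:
    sequence: str
    n_substitutions: int
    n_indels: int

    @property
    def n_events(self) -> int:
        return self.n_substitutions + self.n_indels


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    at = (1.0 - gc) / 2.0
    codes = rng.choice(4, size=length, p=[at, gc / 2, gc / 2, at])
    return _BASES[codes].tobytes().decode("ascii")


def mutate_sequence(
    seq: str,
    rate: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    allow_indels: bool = False,
) -> MutationResult:
    """Mutate a sequence at a per-site event rate; deterministic given seed.

    Substitutions draw uniformly over the three alternative bases.  With
    ``allow_indels``, 10% of mutation events are 1–3 nt insertions or
    deletions instead of substitutions.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    codes = encode(seq).copy()
    n = len(codes)
    hit = np.flatnonzero((rng.random(n) < rate) & (codes < 4))
    indel_positions: list[int] = []
    if allow_indels and hit.size:
        is_indel = rng.random(hit.size) < 0.10
        indel_positions = [int(p) for p in hit[is_indel]]
        hit = hit[~is_indel]
    if hit.size:
        codes[hit] = (codes[hit] + 1 + rng.integers(0, 3, size=hit.size)) % 4
    out = _BASES[np.minimum(codes, 3)].tobytes().decode("ascii")
    # restore Ns (never substituted)
    if (encode(seq) == 4).any():
        chars = list(out)
        for i in np.flatnonzero(encode(seq) == 4):
            chars[i] = "N"
        out = "".join(chars)
    n_indels = 0
    if indel_positions:
        chars = list(out)
        for pos in sorted(indel_positions, reverse=True):
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5:
                del chars[pos : pos + size]
            else:
                chars[pos:pos] = list(random_sequence(rng, size))
            n_indels += 1
        out = "".join(chars)
    return MutationResult(out, int(hit.size), n_indels)


def _segment_identity(donor: str, copy_: str) -> float:
    ea, eb = encode(donor), encode(copy_)
    if len(ea) != len(eb):  # indel-bearing copies: align-free lower bound
        m = min(len(ea), len(eb))
        matches = int(np.sum(ea[:m] == eb[:m]))
        return 100.0 * matches / max(len(ea), len(eb))
    return 100.0 * int(np.sum((ea == eb) & (ea < 4))) / len(ea)


class _Placement:
    """Reserved-interval bookkeeping for one genome."""

    def __init__(self, genome_len: int):
        self.genome_len = genome_len
        self.reserved: list[tuple[int, int]] = []

    def overlaps(self, start: int, end: int) -> bool:
        return any(start < e and s < end for s, e in self.reserved)

    def reserve(self, start: int, end: int) -> None:
        if start < 0 or end > self.genome_len or self.overlaps(start, end):
            raise ValueError("cannot reserve occupied interval")
        self.reserved.append((start, end))

    def choose(self, rng: np.random.Generator, size: int, margin: int = 100) -> int:
        if size + 2 * margin >= self.genome_len:
            raise ValueError("feature does not fit in genome")
        for _ in range(500):
            start = int(rng.integers(margin, self.genome_len - size - margin))
            if not self.overlaps(start - margin, start + size + margin):
                self.reserved.append((start, start + size))
                return start
        raise ValueError("could not place feature: genome too crowded")

    def free_segments(self, extra: list[tuple[int, int]]) -> list[tuple[int, int]]:
        blocks = sorted(self.reserved + extra)
        out = []
        cursor = 0
        for s, e in blocks:
            if s > cursor:
                out.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < self.genome_len:
            out.append((cursor, self.genome_len))
        return out


def _island_runs(
    placed: list[tuple[str, int, int]], max_gap: int = 5000
) -> list[list[str]]:
    """Partition (gene_id, start, end) rows by the <=max_gap proximity rule."""
    runs: list[list[str]] = []
    run: list[str] = []
    prev_end = None
    for gene_id, start, end in sorted(placed, key=lambda r: r[1]):
        if prev_end is not None and start - prev_end > max_gap:
            runs.append(run)
            run = []
        run.append(gene_id)
        prev_end = end if prev_end is None else max(prev_end, end)
    if run:
        runs.append(run)
    return runs


def generate_community(
    config: SyntheticConfig,
    detect_min_identity: float = 99.0,
    detect_min_length: int = 500,
) -> tuple[list[GenomeRecord], TruthSet, dict[str, dict[str, str]]]:
    """Build the community, its ground truth, and a metadata table.

    Returns ``(genomes, truth, metadata)`` where metadata maps genome_id to
    species/genus/phylum labels (relatives share genus and phylum).
    """
    rng = np.random.default_rng(config.seed)
    ids = config.genome_ids()
    id_set = set(ids)
    for spec in config.planted_islands:
        unknown = set(spec.members) - id_set
        if unknown:
            raise ValueError(f"island {spec.spec_id}: unknown genomes {sorted(unknown)}")
    derived_from: dict[str, tuple[str, float]] = {}
    for a, b, rate in config.relative_pairs:
        if a not in id_set or b not in id_set:
            raise ValueError(f"relative pair ({a}, {b}) references unknown genome")
        if b in derived_from:
            raise ValueError(f"genome {b} derived twice")
        derived_from[b] = (a, rate)

    placements = {g: _Placement(config.genome_length) for g in ids}

    # ---- planted island loci -------------------------------------------
    island_loci: dict[tuple[str, str], int] = {}  # (spec_id, genome) -> start
    for spec in config.planted_islands:
        for genome in spec.members:
            island_loci[(spec.spec_id, genome)] = placements[genome].choose(
                rng, spec.cassette_length
            )

    # ---- transposon loci ------------------------------------------------
    # Each element is copied adjacent to one occurrence of each island spec
    # (rotating over recipients so different specs are bridged in different
    # genomes), plus optional scattered copies at random loci.
    transposon_loci: dict[str, list[tuple[str, int]]] = {}
    for e in range(config.confounder_transposons):
        tn_id = f"tn{e + 1}"
        copies: list[tuple[str, int]] = []
        for si, spec in enumerate(config.planted_islands):
            members = spec.recipient_genomes or (spec.donor_genome,)
            genome = members[(e + si) % len(members)]
            isl_start = island_loci[(spec.spec_id, genome)]
            isl_end = isl_start + spec.cassette_length
            placed = False
            for gap in (200, 600, 1200, 2400, 3600):
                for start in (isl_end + gap, isl_start - gap - config.transposon_length):
                    pl = placements[genome]
                    end = start + config.transposon_length
                    if 0 <= start and end <= pl.genome_len and not pl.overlaps(start, end):
                        pl.reserve(start, end)
                        copies.append((genome, start))
                        placed = True
                        break
                if placed:
                    break
            if not placed:
                raise ValueError(f"cannot place transposon {tn_id} next to {spec.spec_id}")
        used = {g for g, _ in copies}
        scatter_targets = [g for g in ids if g not in used] or ids
        for s in range(config.transposon_scatter):
            genome = scatter_targets[s % len(scatter_targets)]
            copies.append(
                (genome, placements[genome].choose(rng, config.transposon_length))
            )
        if not config.planted_islands and not copies:
            for genome in ids[: max(2, min(3, len(ids)))]:
                copies.append(
                    (genome, placements[genome].choose(rng, config.transposon_length))
                )
        transposon_loci[tn_id] = copies

    # ---- background gene intervals (shared within a relative family) ----
    roots = [g for g in ids if g not in derived_from]
    family: dict[str, list[str]] = {r: [r] for r in roots}
    for child, (parent, _) in derived_from.items():
        # walk to the family root
        root = parent
        while root in derived_from:
            root = derived_from[root][0]
        family[root].append(child)

    lo, hi = config.gene_length_range
    background_intervals: dict[str, list[tuple[int, int, str]]] = {}
    for root, members in family.items():
        blocked: list[tuple[int, int]] = []
        for m in members:
            blocked.extend(placements[m].reserved)
        segments = placements[root].free_segments(blocked)
        intervals: list[tuple[int, int, str]] = []
        for seg_start, seg_end in segments:
            cursor = seg_start
            while len(intervals) < config.genes_per_genome:
                cursor += int(rng.integers(50, 301))
                length = int(rng.integers(lo, hi + 1))
                if cursor + length + 50 > seg_end:
                    break
                strand = "+" if rng.random() < 0.5 else "-"
                intervals.append((cursor, cursor + length, strand))
                cursor += length
            if len(intervals) >= config.genes_per_genome:
                break
        if len(intervals) < config.genes_per_genome:
            raise ValueError(
                f"genome {root}: only {len(intervals)} of {config.genes_per_genome} "
                "background genes fit; reduce genes_per_genome or island load"
            )
        for m in members:
            background_intervals[m] = intervals

    # ---- sequences ------------------------------------------------------
    sequences: dict[str, np.ndarray] = {}

    def seq_bytes(s: str) -> np.ndarray:
        return np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy()

    for root in roots:
        sequences[root] = seq_bytes(
            random_sequence(rng, config.genome_length, config.gc_content)
        )
    relative_expected = []
    for a, b, rate in config.relative_pairs:
        base = sequences[a].tobytes().decode("ascii")
        mut = mutate_sequence(base, rate, rng=rng)
        sequences[b] = seq_bytes(mut.sequence)
        relative_expected.append((a, b, 100.0 * (1.0 - rate)))

    # ---- write island cassettes and register planted features ----------
    planted_feats: dict[str, list[dict]] = {g: [] for g in ids}

    for spec in config.planted_islands:
        lengths = spec.resolved_lengths()
        gaps = spec.resolved_gaps()
        gene_seqs = [random_sequence(rng, L, config.gc_content) for L in lengths]
        gap_seqs = [random_sequence(rng, g, config.gc_content) for g in gaps]
        cassette = gene_seqs[0]
        offsets = [0]
        for gseq, gapseq in zip(gene_seqs[1:], gap_seqs):
            cassette += gapseq
            offsets.append(len(cassette))
            cassette += gseq
        for genome in spec.members:
            if genome == spec.donor_genome:
                copy_, identities = cassette, [100.0] * spec.n_genes
            else:
                copy_ = mutate_sequence(cassette, spec.per_site_divergence, rng=rng).sequence
                identities = [
                    _segment_identity(
                        cassette[off : off + L], copy_[off : off + L]
                    )
                    for off, L in zip(offsets, lengths)
                ]
            start = island_loci[(spec.spec_id, genome)]
            sequences[genome][start : start + len(copy_)] = seq_bytes(copy_)
            for gi, (off, L) in enumerate(zip(offsets, lengths)):
                planted_feats[genome].append(
                    {
                        "start": start + off,
                        "end": start + off + L,
                        "strand": "+",
                        "product": _ISLAND_PRODUCTS[gi % len(_ISLAND_PRODUCTS)],
                        "spec": spec.spec_id,
                        "gene_index": gi,
                        "identity": identities[gi],
                    }
                )

    for tn_id, copies in transposon_loci.items():
        tn_seq = random_sequence(rng, config.transposon_length, config.gc_content)
        for genome, start in copies:
            sequences[genome][start : start + len(tn_seq)] = seq_bytes(tn_seq)
            planted_feats[genome].append(
                {
                    "start": start,
                    "end": start + len(tn_seq),
                    "strand": "+",
                    "product": _TRANSPOSON_PRODUCT,
                    "spec": tn_id,
                    "gene_index": 0,
                    "identity": 100.0,
                }
            )

    # ---- assemble GenomeRecords and truth -------------------------------
    phyla = ("Actinomycetota", "Pseudomonadota")
    meta: dict[str, dict[str, str]] = {}
    genus_of: dict[str, str] = {}
    phylum_of: dict[str, str] = {}
    for i, root in enumerate(roots):
        genus_of[root] = f"Genus{i + 1}"
        phylum_of[root] = phyla[i % 2]
    for child, (parent, _) in derived_from.items():
        root = parent
        while root in derived_from:
            root = derived_from[root][0]
        genus_of[child] = genus_of[root]
        phylum_of[child] = phylum_of[root]

    genomes: list[GenomeRecord] = []
    planted: list[PlantedGene] = []
    transposon_copy_genomes = {
        tn: {g for g, _ in copies} for tn, copies in transposon_loci.items()
    }
    spec_by_id = {s.spec_id: s for s in config.planted_islands}
    placed_rows: dict[str, list[tuple[str, str, int, int, float]]] = {g: [] for g in ids}

    for genome_id in ids:
        contig_id = f"{genome_id}_c1"
        seq = sequences[genome_id].tobytes().decode("ascii")
        rows: list[dict] = []
        for start, end, strand in background_intervals[genome_id]:
            rows.append(
                {
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "product": _BACKGROUND_PRODUCT,
                    "spec": None,
                }
            )
        rows.extend(planted_feats[genome_id])
        rows.sort(key=lambda r: r["start"])
        feats = []
        from ._seq import revcomp as _rc

        for i, row in enumerate(rows, 1):
            gene_id = f"{genome_id}_{i:04d}"
            raw = seq[row["start"] : row["end"]]
            feats.append(
                CDSFeature(
                    gene_id,
                    contig_id,
                    row["start"],
                    row["end"],
                    row["strand"],
                    raw if row["strand"] == "+" else _rc(raw),
                    row["product"],
                )
            )
            if row["spec"] is not None:
                placed_rows[genome_id].append(
                    (gene_id, row["spec"], row["start"], row["end"], row["identity"])
                )
        genomes.append(
            GenomeRecord(
                genome_id,
                [Contig(contig_id, seq)],
                feats,
                species_label=f"Species_{genome_id}",
                genus=genus_of[genome_id],
                phylum=phylum_of[genome_id],
            )
        )
        meta[genome_id] = {
            "genome_id": genome_id,
            "species_label": f"Species_{genome_id}",
            "genus": genus_of[genome_id],
            "phylum": phylum_of[genome_id],
        }

    # detectability: a copy can be found iff it keeps >= min identity to the
    # donor copy and is long enough; a donor copy needs a detectable partner
    detectable_map: dict[tuple[str, str], bool] = {}
    per_spec_gene: dict[tuple[str, int], list[tuple[str, str, float, int]]] = {}
    for genome_id in ids:
        counters: dict[str, int] = {}
        for gene_id, spec_id, start, end, identity in sorted(
            placed_rows[genome_id], key=lambda r: r[2]
        ):
            gi = counters.get(spec_id, 0)
            if spec_id in spec_by_id:
                # order within the cassette equals order along the genome
                counters[spec_id] = gi + 1
            per_spec_gene.setdefault((spec_id, gi), []).append(
                (genome_id, gene_id, identity, end - start)
            )
    for (spec_id, gi), copies in per_spec_gene.items():
        spec = spec_by_id.get(spec_id)
        donor = spec.donor_genome if spec else None
        for genome_id, gene_id, identity, length in copies:
            ok_len = length >= detect_min_length
            if spec is None:
                # transposon: verbatim copies, detectable with >=2 genomes
                genomes_with = transposon_copy_genomes[spec_id]
                detectable_map[(genome_id, gene_id)] = ok_len and len(genomes_with) >= 2
            elif genome_id == donor:
                partner_ok = any(
                    g != donor and ident >= detect_min_identity and L >= detect_min_length
                    for g, _, ident, L in copies
                )
                detectable_map[(genome_id, gene_id)] = ok_len and partner_ok
            else:
                detectable_map[(genome_id, gene_id)] = (
                    ok_len and identity >= detect_min_identity
                )

    expected_islands: dict[str, list[list[str]]] = {}
    expected_groups: dict[str, list[list[str]]] = {}
    transposon_genes: list[tuple[str, str]] = []
    for genome_id in ids:
        rows = [
            (gene_id, start, end)
            for gene_id, spec_id, start, end, _ in placed_rows[genome_id]
            if detectable_map[(genome_id, gene_id)]
        ]
        if rows:
            expected_islands[genome_id] = _island_runs(rows)
    for genome_id in ids:
        for gene_id, spec_id, start, end, identity in placed_rows[genome_id]:
            det = detectable_map[(genome_id, gene_id)]
            planted.append(PlantedGene(genome_id, gene_id, spec_id, identity, det))
            if det:
                expected_groups.setdefault(spec_id, []).append([genome_id, gene_id])
            if spec_id not in spec_by_id:
                transposon_genes.append((genome_id, gene_id))

    truth = TruthSet(
        planted=planted,
        expected_islands=expected_islands,
        expected_groups=expected_groups,
        relative_expected_ani=relative_expected,
        transposon_genes=transposon_genes,
        detect_min_identity=detect_min_identity,
        detect_min_length=detect_min_length,
    )
    return genomes, truth, meta


@dataclass
class RecoveryMetrics:
    gene_precision: float
    gene_recall: float
    island_exact_fraction: float
    group_pair_precision: float
    group_pair_recall: float
    no_detections: bool = False
    no_predicted_pairs: bool = False

    def as_dict(self) -> dict:
        return {
            "gene_precision": self.gene_precision,
            "gene_recall": self.gene_recall,
            "island_exact_fraction": self.island_exact_fraction,
            "group_pair_precision": self.group_pair_precision,
            "group_pair_recall": self.group_pair_recall,
            "no_detections": self.no_detections,
            "no_predicted_pairs": self.no_predicted_pairs,
        }


def evaluate_recovery(candidates, islands, groups, truth: TruthSet) -> RecoveryMetrics:
    """Score a detection run against the planted ground truth.

    Gene precision is measured against all planted genes (a hit on a planted
    copy marked undetectable is still a true transfer); recall against the
    detectable ones.  Group scoring compares pairwise co-membership of
    detected planted genes: truth puts two genes together iff they descend
    from the same island spec (or transposon element).  With no detections,
    precision conventions report 1.0 and set ``no_detections``.
    """
    detected = set(candidates.keys() if hasattr(candidates, "keys") else candidates)
    truth_genomes = {p.genome_id for p in truth.planted}
    planted = truth.planted_keys()
    detectable = truth.detectable_keys()
    if detected and truth_genomes and not ({g for g, _ in detected} & truth_genomes):
        raise ValueError("detection output and truth share no genome ids")

    no_detections = not detected
    gene_precision = (
        1.0 if no_detections else len(detected & planted) / len(detected)
    )
    gene_recall = (
        1.0 if not detectable else len(detected & detectable) / len(detectable)
    )

    detected_island_sets = {
        (isl.genome_id, frozenset(g.gene_id for g in isl.genes)) for isl in islands
    }
    truth_islands = [
        (genome, frozenset(run))
        for genome, runs in truth.expected_islands.items()
        for run in runs
    ]
    island_exact = (
        sum(1 for t in truth_islands if t in detected_island_sets) / len(truth_islands)
        if truth_islands
        else 1.0
    )

    spec_of = truth.spec_of()
    scored = sorted(detected & planted)
    group_of: dict[tuple[str, str], int] = {}
    for grp in groups:
        for key in grp.gene_keys:
            group_of[key] = grp.group_rank
    pred_pairs = set()
    true_pairs = set()
    for i, a in enumerate(scored):
        for b in scored[i + 1 :]:
            pair = (a, b)
            if group_of.get(a) is not None and group_of.get(a) == group_of.get(b):
                pred_pairs.add(pair)
            if spec_of[a] == spec_of[b]:
                true_pairs.add(pair)
    no_pred = not pred_pairs
    group_precision = 1.0 if no_pred else len(pred_pairs & true_pairs) / len(pred_pairs)
    group_recall = (
        1.0 if not true_pairs else len(pred_pairs & true_pairs) / len(true_pairs)
    )
    return RecoveryMetrics(
        gene_precision,
        gene_recall,
        island_exact,
        group_precision,
        group_recall,
        no_detections,
        no_pred,
    )


def write_community(
    genomes: Sequence[GenomeRecord],
    truth: TruthSet,
    meta: dict[str, dict[str, str]],
    out_dir: str | os.PathLike,
) -> None:
    """Persist the community as FASTA + GFF3 + metadata TSV + truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for g in genomes:
        with open(out / f"{g.genome_id}.fasta", "w") as fh:
            for c in g.contigs:
                fh.write(f">{c.contig_id}\n")
                for i in range(0, len(c.sequence), 70):
                    fh.write(c.sequence[i : i + 70] + "\n")
        with open(out / f"{g.genome_id}.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for f in g.features:
                product = f.product.replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")
                fh.write(
                    f"{f.contig_id}\thgtscan_sim\tCDS\t{f.start + 1}\t{f.end}\t.\t"
                    f"{f.strand}\t0\tID={f.gene_id};product={product}\n"
                )
    with open(out / "metadata.tsv", "w") as fh:
        fh.write("genome_id\tspecies_label\tgenus\tphylum\n")
        for g in genomes:
            row = meta[g.genome_id]
            fh.write(
                f"{row['genome_id']}\t{row['species_label']}\t{row['genus']}\t{row['phylum']}\n"
            )
    truth.to_json(out / "truth.json")
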