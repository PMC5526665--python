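"""Parsing annotated bacterial genomes into a uniform internal model.

Genomes arrive either as GenBank flat files (one or more contigs per file,
CDS features annotated) or as a FASTA of contigs with a GFF3 sidecar carrying
the CDS lines.  Coordinates are converted on read from the 1-based inclusive
convention of both formats to 0-based half-open intervals; CDS on the minus
strand store the reverse-complemented (strand-resolved) sequence.

Compound locations (``join``/``complement(join)``) confined to one contig are
flattened to their min-start..max-end envelope; features spanning contigs or
running past the contig end are skipped and counted in the parse report.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable
from urllib.parse import unquote

from Bio import SeqIO

from ._seq import revcomp, sanitize


@dataclass(frozen=True)
class Contig:
    contig_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CDSFeature:
    """A protein-coding gene: 0-based half-open interval on one contig."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    nt_sequence: str
    product: str = ""

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if len(self.nt_sequence) != self.end - self.start:
            raise ValueError("nt_sequence length does not match interval")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    genome_id: str
    contigs: list[Contig]
    features: list[CDSFeature]
    species_label: str = ""
    genus: str = ""
    phylum: str = ""

    def __post_init__(self):
        if not self.genome_id or any(c in self.genome_id for c in " \t/\\"):
            raise ValueError(f"bad genome_id {self.genome_id!r}")
        by_id = {c.contig_id: c for c in self.contigs}
        if len(by_id) != len(self.contigs):
            raise ValueError("duplicate contig ids")
        seen = set()
        for f in self.features:
            if f.contig_id not in by_id:
                raise ValueError(f"feature {f.gene_id} on unknown contig {f.contig_id}")
            if f.gene_id in seen:
                raise ValueError(f"duplicate gene_id {f.gene_id}")
            seen.add(f.gene_id)

    def contig(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.contig_id == contig_id:
                return c
        raise KeyError(contig_id)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.contigs)


@dataclass
class ParseReport:
    n_contigs: int = 0
    n_cds: int = 0
    n_skipped: int = 0
    skipped: list[str] = field(default_factory=list)


class GenomeParseError(Exception):
    """Unreadable input or a genome with no usable CDS features."""


def _feature_from_interval(
    gene_id: str, contig: Contig, start: int, end: int, strand: str, product: str
) -> CDSFeature:
    raw = contig.sequence[start:end]
    seq = raw if strand == "+" else revcomp(raw)
    return CDSFeature(gene_id, contig.contig_id, start, end, strand, seq, product)


def _read_genbank(path: Path, genome_id: str):
    contigs: list[Contig] = []
    feats: list[CDSFeature] = []
    report = ParseReport()
    serial = 0
    for rec in SeqIO.parse(str(path), "genbank"):
        contig = Contig(rec.id, sanitize(str(rec.seq)))
        contigs.append(contig)
        for f in rec.features:
            if f.type != "CDS":
                continue
            serial += 1
            gene_id = (
                f.qualifiers.get("locus_tag", [None])[0]
                or f.qualifiers.get("protein_id", [None])[0]
                or f"cds_{serial:05d}"
            )
            product = f.qualifiers.get("product", [""])[0]
            if any(part.ref for part in f.location.parts):
                # join() across records cannot be resolved to one interval
                report.n_skipped += 1
                report.skipped.append(gene_id)
                continue
            start = int(f.location.start)
            end = int(f.location.end)
            if start < 0 or end > contig.length or start >= end:
                report.n_skipped += 1
                report.skipped.append(gene_id)
                continue
            strand = "-" if f.location.strand == -1 else "+"
            feats.append(_feature_from_interval(gene_id, contig, start, end, strand, product))
    report.n_contigs = len(contigs)
    report.n_cds = len(feats)
    return contigs, feats, report


def _parse_gff3_attrs(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = unquote(v.strip())
    return out


def _read_fasta_gff3(fasta: Path, gff3: Path, genome_id: str):
    contigs = [
        Contig(rec.id, sanitize(str(rec.seq))) for rec in SeqIO.parse(str(fasta), "fasta")
    ]
    by_id = {c.contig_id: c for c in contigs}
    feats: list[CDSFeature] = []
    report = ParseReport(n_contigs=len(contigs))
    serial = 0
    with open(gff3) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GenomeParseError(f"{gff3}:{lineno}: expected 9 columns")
            seqid, _, ftype, start_s, end_s, _, strand, _, attrs = cols
            if ftype != "CDS":
                continue
            serial += 1
            attr = _parse_gff3_attrs(attrs)
            gene_id = attr.get("ID") or attr.get("locus_tag") or f"cds_{serial:05d}"
            start = int(start_s) - 1  # GFF3 is 1-based inclusive
            end = int(end_s)
            contig = by_id.get(seqid)
            if contig is None or start < 0 or end > contig.length or start >= end:
                report.n_skipped += 1
                report.skipped.append(gene_id)
                continue
            strand = "-" if strand == "-" else "+"
            feats.append(
                _feature_from_interval(
                    gene_id, contig, start, end, strand, attr.get("product", "")
                )
            )
    report.n_cds = len(feats)
    return contigs, feats, report


def read_genome(
    path: str | os.PathLike,
    format_hint: str = "auto",
    genome_id: str | None = None,
    gff3_path: str | os.PathLike | None = None,
    allow_empty: bool = False,
) -> tuple[GenomeRecord, ParseReport]:
    """Parse one annotated genome.

    ``path`` is a GenBank file, or a FASTA whose CDS annotation lives in
    ``gff3_path`` (default: same stem with a ``.gff3``/``.gff`` suffix).
    Returns the parsed record together with a :class:`ParseReport` counting
    skipped (unresolvable) features.  A genome in which no CDS could be
    parsed raises :class:`GenomeParseError` unless ``allow_empty`` is set.
    """
    path = Path(path)
    if not path.exists():
        raise GenomeParseError(f"no such file: {path}")
    if genome_id is None:
        genome_id = path.stem
    fmt = format_hint
    if fmt == "auto":
        fmt = "genbank" if path.suffix.lower() in {".gb", ".gbk", ".gbff", ".genbank"} else "fasta+gff3"
    if fmt == "genbank":
        contigs, feats, report = _read_genbank(path, genome_id)
    elif fmt == "fasta+gff3":
        if gff3_path is None:
            for suffix in (".gff3", ".gff"):
                cand = path.with_suffix(suffix)
                if cand.exists():
                    gff3_path = cand
                    break
        if gff3_path is None:
            raise GenomeParseError(f"no GFF3 sidecar found for {path}")
        contigs, feats, report = _read_fasta_gff3(path, Path(gff3_path), genome_id)
    else:
        raise ValueError(f"unknown format_hint {format_hint!r}")
    if not contigs:
        raise GenomeParseError(f"no sequence records in {path}")
    if not feats and not allow_empty:
        raise GenomeParseError(f"no CDS features parsed from {path}")
    return GenomeRecord(genome_id, contigs, feats), report


def read_genome_dir(
    directory: str | os.PathLike, metadata: dict[str, dict[str, str]] | None = None
) -> list[GenomeRecord]:
    """Parse every genome file in a directory (GenBank or FASTA+GFF3 pairs)."""
    directory = Path(directory)
    genomes = []
    for p in sorted(directory.iterdir()):
        if p.suffix.lower() in {".gb", ".gbk", ".gbff", ".genbank", ".fasta", ".fa", ".fna"}:
            rec, _ = read_genome(p)
            if metadata and rec.genome_id in metadata:
                m = metadata[rec.genome_id]
                rec.species_label = m.get("species_label", "")
                rec.genus = m.get("genus", "")
                rec.phylum = m.get("phylum", "")
            genomes.append(rec)
    if not genomes:
        raise GenomeParseError(f"no genome files found in {directory}")
    return genomes


def read_metadata(path: str | os.PathLike) -> dict[str, dict[str, str]]:
    """Read the genome metadata TSV (genome_id, species_label, genus, phylum)."""
    path = Path(path)
    out: dict[str, dict[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = {"genome_id", "species_label"}
        if not required <= set(header):
            raise ValueError(f"metadata {path} must have columns genome_id, species_label")
        for line in fh:
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            out[row["genome_id"]] = row
    return out


def write_gene_fasta(genome: GenomeRecord, out: str | os.PathLike) -> int:
    """One FASTA record per CDS, headers ``genome_id|gene_id``; returns count."""
    if not genome.features:
        raise ValueError(f"genome {genome.genome_id} has no CDS to write")
    with open(out, "w") as fh:
        for f in genome.features:
            fh.write(f">{genome.genome_id}|{f.gene_id}\n")
            for i in range(0, len(f.nt_sequence), 70):
                fh.write(f.nt_sequence[i : i + 70] + "\n")
    return len(genome.features)


def write_genes_table(genomes: Iterable[GenomeRecord], out: str | os.PathLike) -> int:
    """TSV of all CDS across genomes; returns number of rows written."""
    n = 0
    with open(out, "w") as fh:
        fh.write("genome_id\tgene_id\tcontig_id\tstart\tend\tstrand\tlength\tproduct\n")
        for g in genomes:
            for f in g.features:
                fh.write(
                    f"{g.genome_id}\t{f.gene_id}\t{f.contig_id}\t{f.start}\t{f.end}"
                    f"\t{f.strand}\t{f.length}\t{f.product}\n"
                )
                n += 1
    return n


def write_contig_fasta(genome: GenomeRecord, out: str | os.PathLike) -> int:
    """Write the genome's contigs as FASTA; returns contig count."""
    with open(out, "w") as fh:
        for c in genome.contigs:
            fh.write(f">{c.contig_id}\n")
            for i in range(0, len(c.sequence), 70):
                fh.write(c.sequence[i : i + 70] + "\n")
    return len(genome.contigs)
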