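"""Functional tallies and per-genome/per-group summaries of detected genes.

Functional categories (typically KEGG KO/module labels produced by an
external annotator) arrive as a TSV; this module only counts.  Two
denominators are meaningful and both are supported: all detected CDS, or
only the annotated ones.  Raw counts are always authoritative; percentages
are additionally formatted for display in the mixed style common in
comparative-genomics reports (see :func:`format_percent`).
"""
from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Mapping, Sequence

from .detection import CandidateGene, HGTGroup, Island
from .genome_io import GenomeRecord


@dataclass(frozen=True)
class FunctionAnnotation:
    gene_id: tuple[str, str]  # genome-qualified
    category_id: str
    category_name: str


@dataclass(frozen=True)
class CategoryTally:
    category_id: str
    category_name: str
    n_genes: int
    denom: int
    denom_mode: str

    @property
    def fraction(self) -> float:
        return 100.0 * self.n_genes / self.denom if self.denom else 0.0

    @property
    def display(self) -> str:
        return format_percent(self.n_genes, self.denom, style="tally")


def format_percent(numerator: int, denominator: int, style: str = "tally") -> str:
    """Render ``numerator/denominator`` as a display percentage.

    ``tally`` style (gene-category fractions): integer percent at >=10%,
    one decimal below 10% (e.g. 631/4733 -> "13", 63/2264 -> "2.8").
    ``one_decimal`` style (genome/group shares): always one decimal
    (e.g. 130/165 -> "78.8").  Raw counts stay the authoritative record;
    this is presentation only.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = 100.0 * numerator / denominator
    if style == "one_decimal":
        return f"{pct:.1f}"
    if style == "tally":
        return f"{pct:.0f}" if pct >= 10 else f"{pct:.1f}"
    raise ValueError(f"unknown style {style!r}")


def load_annotations(path: str | os.PathLike) -> dict[tuple[str, str], list[FunctionAnnotation]]:
    """Read a gene->category TSV keyed ``genome_id|gene_id`` (or with separate
    genome_id and gene_id columns); duplicates are collapsed."""
    out: dict[tuple[str, str], list[FunctionAnnotation]] = {}
    seen: set[tuple] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {name: i for i, name in enumerate(header)}
        if "category_id" not in cols or "category_name" not in cols:
            raise ValueError(f"{path}: need columns gene_id, category_id, category_name")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            row = line.rstrip("\n").split("\t")
            if "genome_id" in cols:
                key = (row[cols["genome_id"]], row[cols["gene_id"]])
            else:
                ident = row[cols["gene_id"]]
                if "|" not in ident:
                    raise ValueError(f"{path}:{lineno}: gene_id must be genome_id|gene_id")
                key = tuple(ident.split("|", 1))
            dedup = (key, row[cols["category_id"]])
            if dedup in seen:
                continue
            seen.add(dedup)
            out.setdefault(key, []).append(
                FunctionAnnotation(key, row[cols["category_id"]], row[cols["category_name"]])
            )
    return out


def tally_categories(
    candidates: Mapping[tuple[str, str], CandidateGene],
    annotations: Mapping[tuple[str, str], list[FunctionAnnotation]],
    denom_mode: str = "annotated_only",
) -> list[CategoryTally]:
    """Count detected genes per functional category.

    ``denom_mode`` 'all_cds' uses every detected gene as the denominator;
    'annotated_only' uses only detected genes with at least one annotation.
    A gene carrying several categories counts once in each (tallies are
    gene-category incidences).
    """
    if denom_mode not in ("all_cds", "annotated_only"):
        raise ValueError(f"unknown denom_mode {denom_mode!r}")
    annotated = [k for k in candidates if k in annotations]
    denom = len(candidates) if denom_mode == "all_cds" else len(annotated)
    counts: dict[tuple[str, str], int] = {}
    for key in annotated:
        for ann in annotations[key]:
            counts[(ann.category_id, ann.category_name)] = (
                counts.get((ann.category_id, ann.category_name), 0) + 1
            )
    tallies = [
        CategoryTally(cid, cname, n, denom, denom_mode)
        for (cid, cname), n in counts.items()
    ]
    tallies.sort(key=lambda t: (-t.n_genes, t.category_id))
    return tallies


@dataclass(frozen=True)
class GenomeSummary:
    genome_id: str
    n_hgt_genes: int
    n_islands: int
    n_groups_touched: int
    frac_of_genome_genes: float


@dataclass(frozen=True)
class SummaryFooter:
    n_genomes: int
    n_with_candidates: int

    @property
    def pct_with_candidates(self) -> str:
        return format_percent(self.n_with_candidates, self.n_genomes, style="one_decimal")


def per_genome_summary(
    candidates: Mapping[tuple[str, str], CandidateGene],
    islands: Sequence[Island],
    groups: Sequence[HGTGroup],
    genomes: Sequence[GenomeRecord],
) -> tuple[list[GenomeSummary], SummaryFooter]:
    """One row per input genome (zero rows included) plus a footer with the
    count and share of genomes carrying at least one candidate gene."""
    rows = []
    for g in sorted(genomes, key=lambda g: g.genome_id):
        keys = {k for k in candidates if k[0] == g.genome_id}
        isl = [i for i in islands if i.genome_id == g.genome_id]
        touched = {
            grp.group_rank
            for grp in groups
            if any(i.genome_id == g.genome_id for i in grp.islands)
        }
        frac = 100.0 * len(keys) / len(g.features) if g.features else 0.0
        rows.append(GenomeSummary(g.genome_id, len(keys), len(isl), len(touched), frac))
    footer = SummaryFooter(len(rows), sum(1 for r in rows if r.n_hgt_genes > 0))
    return rows, footer


def write_summary_tables(
    out_dir: str | os.PathLike,
    tallies: Sequence[CategoryTally],
    genome_rows: Sequence[GenomeSummary],
    footer: SummaryFooter,
) -> None:
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "category_tallies.tsv"), "w") as fh:
        fh.write("category_id\tcategory_name\tn_genes\tdenom\tdenom_mode\tfraction_pct\tdisplay\n")
        for t in tallies:
            fh.write(
                f"{t.category_id}\t{t.category_name}\t{t.n_genes}\t{t.denom}\t"
                f"{t.denom_mode}\t{t.fraction:.4f}\t{t.display}\n"
            )
    with open(os.path.join(out_dir, "per_genome.tsv"), "w") as fh:
        fh.write("genome_id\tn_hgt_genes\tn_islands\tn_groups_touched\tfrac_of_genome_genes_pct\n")
        for r in genome_rows:
            fh.write(
                f"{r.genome_id}\t{r.n_hgt_genes}\t{r.n_islands}\t{r.n_groups_touched}\t"
                f"{r.frac_of_genome_genes:.4f}\n"
            )
        fh.write(
            f"# genomes_with_candidates\t{footer.n_with_candidates}/{footer.n_genomes}"
            f"\t{footer.pct_with_candidates}%\n"
        )
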