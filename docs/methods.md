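# Methods

## The detection model

`hgtscan` detects putative horizontal gene transfer (HGT) in a collection of
annotated bacterial genomes from one signature alone: protein-coding genes
that are *too similar for too long* between genomes that are *too distantly
related* for the similarity to be vertical. The procedure has four stages:

1. **All-vs-all homology search.** Every CDS of every genome is searched
   against the CDS of every other genome. A pair qualifies as a hit when the
   best local alignment reaches `min_identity` (default **99%**) over
   `min_length` (default **500 nt**), both thresholds inclusive. Hits within
   one genome are never emitted; hits between genomes labelled as the same
   species are removed during filtering.
2. **Vertical-inheritance filter.** For every genome pair a fragment-based
   average nucleotide identity (ANI) is computed. Hits between pairs with
   two-way ANI strictly greater than `max_ani` (default **89%**) are
   discarded as likely shared ancestry; everything else is kept. A pair at
   ANI ~88 (the closest-relative regime the method is designed to tolerate)
   passes the filter.
3. **Island assembly.** Within each genome and contig, candidate genes
   (genes incident to at least one retained hit) are merged into islands
   when the boundary-to-boundary gap between consecutive candidates is at
   most `island_max_gap` (default **5000 nt**, inclusive at the boundary).
   Non-candidate genes inside a gap neither join nor split an island.
4. **Group clustering.** Islands across genomes are linked when a retained
   hit joins a gene of one island to a gene of another; groups are the
   connected components of that graph. Membership is transitive: islands
   with no directly shared gene co-cluster through intermediates. Groups are
   ranked by total gene count, ties broken by nucleotide content and then by
   smallest member genome id, so reports are fully deterministic.

The method is symmetric and says nothing about direction: it identifies
regions that moved, not who donated them.

### Known artifact: mobile-element chaining

A transposase (or any short mobile gene) present near unrelated islands in
different genomes chains those islands into a single group. This is a
property of transitive clustering, and it is deliberately *reported, not
corrected*: genes whose retained hits touch more than
`promiscuous_min_genomes` distinct genomes (default 10, appropriate for
collections of >100 genomes; use ~3 for a handful of genomes) are flagged
in the candidates table, but groups are never auto-split. The synthetic
confounder scenario reproduces and tests exactly this behaviour.

## Alignment engine

The search targets near-identical alignments, so an exact-seed strategy is
sufficient and fast: 31-mer seeds shared between query and subject are
extended in both directions with banded (band ±16), affine-gap
(open −4, extend −2; match +1, mismatch −2) dynamic programming under an
X-drop of 20. Identity counts gap columns in the denominator, matching the
convention of 12-column tabular hit files, which the package also ingests
and emits for interoperability with external search tools. `N` never counts
as a match, including against `N`. Overlapping alignments are collapsed
keeping the highest score; per gene pair only the best-scoring alignment is
kept (ties by smaller query then subject start).

Two tie-break conventions make results reproducible and testable: extension
stops at the first running-maximum (of co-optimal alignments the shortest is
reported), and the exhaustive Smith–Waterman reference (`smith_waterman`,
kept for validation) restarts its local path at score ≤ 0 so that it prefers
the same co-optimal alignment. On substitution-only divergence up to ~5%
the seeded aligner reproduces the exhaustive optimum exactly (score,
matches, columns); this is asserted over randomized pairs in the test suite
and recomputed by the acceptance script. At 99% identity over ≥500 nt, an
intact 31-mer seed exists with overwhelming probability; the X-drop of 20
tolerates the mismatch runs expected at up to ~10% divergence (a 20-point
dip requires ~7 near-adjacent mismatches, vanishingly rare below that).

Dynamic-programming kernels are scalar loops compiled with numba when
available, with a pure-Python fallback that is slow but identical.

## ANI estimator

Fragment-based, in the classic style: non-overlapping 1000-nt tiles of
genome A are each aligned against all of genome B (k = 15 seeds, permissive
thresholds); a tile qualifies if its best hit has ≥70% identity over ≥70%
of the tile. One-way ANI is the mean best-hit identity over qualifying
tiles; the reported value is the mean of the two directions. Terminal tiles
shorter than half a fragment are dropped.

A direction is **defined** only if (a) at least `min_fragments` (5) tiles
qualify and (b) qualifying tiles are at least `min_fragment_fraction` (20%)
of the direction's tiles. Guard (b) is the aligned-fraction convention of
whole-genome ANI practice, and it matters here: two unrelated genomes that
exchanged a single island align over exactly those few tiles at ~100%
identity, and without the guard they would masquerade as close relatives
and be filtered — deleting precisely the transfers the method exists to
find. True relatives align over essentially all tiles, so any fraction well
below 1 and well above the island share behaves identically. An undefined
ANI is treated downstream as "distant": the pair is *not* excluded, because
the filter exists only to remove close relatives.

Whole contigs, not CDS, are fragmented. On substitution-only pairs the
estimator tracks the simulated rate closely (|ANI − 100(1−r)| ≤ 0.3 points
at r up to 0.1 on 50-kb genomes; the residual error is dominated by the
binomial noise of the mutation process itself) and self-comparison is
exactly 100.

## Metagenome screening

Each CDS of a marker region is searched against the contigs of each
assembled metagenome (k = 21 seeds, both strands). A CDS is *present* when
some alignment is **strictly** above `min_identity` (default 97%) and
covers at least `min_query_coverage` (default 90%) of the CDS. The coverage
requirement is this package's addition: identity over a trivial fragment
should not count a gene as present. Output is a per-region presence/absence
matrix (rows = CDS in region order, columns = metagenomes) plus counts of
metagenomes containing ≥1 and all CDS.

## Synthetic communities

The generator is the package's primary validation surface. Each community
is built from a single integer seed and is byte-reproducible.

* **Backgrounds**: i.i.d. random sequence at a target GC (default 0.50 — a
  neutral midpoint; real taxa range roughly 0.35–0.65 and nothing in the
  pipeline is GC-sensitive), default 100 kb per genome with 60 background
  genes of 600–1500 nt. These sizes keep a full 8-genome pipeline run in
  tens of seconds while leaving islands a small minority of each genome.
* **Vertical relatives**: a pair (A, B, r) gives B the sequence of A
  mutated at per-site substitution rate r, with background gene intervals
  shared, so the pair's expected ANI is 100(1−r) and every background gene
  is a vertical homolog.
* **Planted islands**: a cassette of n genes (default 800 nt each,
  200-nt gaps) is written into the donor and each recipient at random
  non-overlapping loci, mutated at the island's per-site divergence on
  copy. Realized per-gene identity versus the donor copy is recorded
  exactly (Hamming; divergence is substitution-only by default so
  identities have closed form).
* **Transposon confounders**: each element is one 1.2-kb sequence copied
  verbatim adjacent (within the island gap) to one occurrence of *each*
  island spec — rotating over recipients so different specs are bridged in
  different genomes — plus `transposon_scatter` (default 4) scattered
  copies in further genomes. This deterministic placement guarantees the
  group-merge artifact the pipeline must reproduce and flag, while the
  scattered copies give the element the many-genome hit pattern that the
  promiscuity diagnostic looks for.

**Ground truth** marks each planted copy *detectable* iff its realized
identity to the donor copy meets the detection thresholds (≥99% and
≥500 nt), so recall is measured against what the thresholds permit, not
against generator noise. Expected islands are computed from the planted
coordinates with the same ≤5-kb rule the detector uses (so a transposon
copy planted adjacent to an island belongs to that island in truth too);
the expected group partition is one group per island spec and per
transposon element.

`evaluate_recovery` scores gene precision (against all planted genes — a
hit on a planted-but-undetectable copy is still a true transfer), gene
recall (against detectable ones), exact island recovery, and pairwise group
co-membership precision/recall over detected planted genes. Degenerate
conventions: empty detection reports precision 1.0 with a `no_detections`
flag and recall 0.

### What the generator does not emulate

Real gene boundaries (ORFs, codon structure), rearrangements, gene loss,
homologous recombination, GC skew, repeat families beyond the single
transposon element, and assembly fragmentation. Passing the synthetic suite
therefore demonstrates the *logic* of the pipeline — thresholds, filters,
proximity and clustering rules, confounder behaviour — not robustness to
annotation noise or draft-assembly artifacts in real data.

## Numerical and formatting choices

* Coordinates are 0-based half-open internally; GenBank/GFF3 1-based
  inclusive are converted on read. Compound locations within a contig are
  flattened to their envelope; cross-contig joins are skipped and counted.
* Ambiguity codes other than N are mapped to N on read; N is a universal
  mismatch.
* Identity thresholds compare with a 1e-9 tolerance so that printed
  boundary values (99.0, 500) behave inclusively.
* Display percentages follow the mixed style of comparative-genomics
  reports: gene-category tallies print integer percent at ≥10% and one
  decimal below; genome- and group-level shares always print one decimal.
  Raw counts are always emitted and are the authoritative record.
* Group statistics with missing genus/phylum labels report `unknown`
  (None), never false.

## Problem sizes used in validation

The bundled validation scenario is 8 genomes × 100 kb with two planted
islands (5 genes verbatim; 4 genes at 0.5% divergence), one relative pair
at 5% divergence, and one scattered transposon element; ANI calibration
uses 50-kb pairs at r ∈ {0.005, 0.01, 0.05, 0.1}; aligner–reference
equivalence uses 100 random pairs of 200–2000 nt; clustering is checked
against a brute-force transitive closure on 50 random island graphs of up
to 50 islands. These sizes were chosen so the whole suite runs in well
under a minute of compute per scenario while every rule (thresholds, gap
boundaries, filter cutoffs, confounder merge) is exercised at its boundary.

## Limitations

* No donor/recipient inference, no phylogenetic (tree-incongruence) HGT
  detection, no ICE/attachment-site or flanking-repeat analysis.
* The ANI filter inherits the usual blind spot of similarity-based HGT
  detection: genuine transfers between very close relatives (ANI above the
  cutoff) are invisible, and the reported gene set is a lower bound that
  depends on the genomes included.
* The internal aligner is tuned for the near-identity regime; it is not a
  general-purpose sensitive aligner, and external tabular hits can be
  supplied where a full BLAST-style search is preferred.
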