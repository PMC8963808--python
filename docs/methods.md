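# Methods

`qtlatlas` builds a quantitative genomic map for *Brassica napus*-style
multi-study QTL inventories: hundreds to thousands of QTLs for agronomic and
disease-related traits, collected from many mapping populations and
countries, are projected onto one physical reference assembly so that
regions where QTLs of several trait categories co-localize — candidate
pleiotropic or linked loci — can be called, and the genes inside them
nominated and ranked by interaction-network degree.

## The model

**Trait categories.** Every trait name is mapped through an explicit catalog
to one of five categories: abiotic factor (A), biotic factor (B), hormone
level (H), seed component (S) and yield-related (Y). The catalog is data,
not code: inventories differ in trait vocabulary, and an uncatalogued trait
rejects the row (with a reason in the curation report) rather than guessing
a category.

**Marker anchoring (e-PCR).** Flanking markers are located on the assembly
by in-silico PCR: the forward primer must match one strand within a Hamming
mismatch budget and the reverse-complement of the reverse primer must match
downstream so that the product size falls in a window; primer roles are also
tried swapped (forward primer on the minus strand). Matching is Hamming-only
(no indels), the classical STS-search model — it keeps the semantics simple
enough that an exhaustive sliding-window scan can serve as an exact oracle
in the tests. Pure-ACGT primers are searched by pigeonhole seeding (split
into `max_mismatch + 1` exact pieces; every admissible match must contain
one piece verbatim) with candidate verification; IUPAC-ambiguous primers
fall back to a vectorized full scan. Ambiguity codes in a primer match their
expansion set; in the genome only concrete A/C/G/T match, and an N matches
nothing (conservative anchoring). A marker's position is the midpoint of its
amplicon (or matched span); multi-hit markers are resolved by
`best_mismatch_then_fail` (keep a unique minimal-mismatch hit, else report
the marker unanchored — never raise, downstream projection decides).

Defaults: `max_mismatch = 1` per primer, product size 50–5,000 bp, both
orientations searched. No standard values exist for these in the STS
literature we model; they are package choices, surfaced in the CLI help and
the run report.

**Projection.** Two anchored markers span `[min, max]` of their positions.
A single anchored marker — single-marker QTLs and GWAS hits are kept, not
dropped — receives a 1-cM window converted at `cm_to_bp` (default
425 kb/cM ≈ 850 Mb over a ~2,000 cM *B. napus* map; overridable per
chromosome). The window is *centered* on the marker (±0.5 cM) by default;
the alternative reading, marker to marker + 1 cM, is available as
`window_anchor="right"` since the convention is genuinely ambiguous in the
field. The half-span is rounded half-up, frozen. Pre-anchored records pass
through after clamping to `[1, chromosome length]`. Markers anchoring to
different chromosomes reject the record. The atlas is canonically sorted by
(chromosome order, start, end, qtl id), so region calling is invariant to
input row order.

**Overlap regions.** Each chromosome is decomposed by sweep line into
maximal *atomic segments* with a constant covering-QTL set (every covered bp
belongs to exactly one segment). An overlap region is a maximal run of
bp-adjacent qualifying segments (≥ `min_categories` = 2 distinct categories
present). Where a region ends is the one genuinely open design choice, so
both conventions are first-class and the run report states which was used:

* `constant_category_set` (default): the run breaks where the *set* of
  present categories changes — regions are homogeneous multi-trait blocks;
* `constant_multiplicity`: the run breaks only where the *number* of
  categories changes, so it can merge across set changes (it never yields
  more regions than the default policy).

Per-category counts are over *distinct* QTLs; a QTL crossing several atomic
segments of one region counts once there, but a long QTL may legitimately
be counted again in other regions. Region multiplicity is the number of
categories with a nonzero count (2–5). Coordinates are exact bp internally;
Mb rounding to two decimals is display-only (which is why very short
regions can print as `2.31–2.31 Mb`).

**Hot and specific regions.** A *hot* region hosts strictly more than
`hot_threshold` = 100 distinct QTLs. A region is environment- (or
population-) specific when all its covering QTLs share one country (or
population) and it hosts at least `specificity_min_qtls` = 2 QTLs — the
minimum stops singleton regions from being trivially "specific".

**Trait-pair co-localization.** For a named pair (e.g. oil content × seed
yield) the same decomposition machinery, restricted to the two traits,
returns the maximal runs of bp covered by at least one QTL of *each* trait.

**Candidate genes and the network.** A gene is a candidate when it
intersects an overlap region — `overlap` mode (≥ 1 shared bp, the default)
or `contained` (gene fully inside); `contained` candidates are always a
subset of `overlap` candidates, and the report states the mode. Candidates
carry the regions they touch, the union of categories and their highest
region multiplicity. The interaction network is consumed as an exported
two-column edge list (deduplicated, self-loops dropped and counted); degree
is the number of incident edges (so Σ degrees = 2·edges always), hubs are
nodes with degree ≥ 60 (inclusive), and nodes are optionally grouped by a
16-class GO-slim biological-process vocabulary shipped as a data file, with
unmapped genes classified "Others". Ortholog mapping (e.g. to
*A. thaliana* identifiers) is an input table, never computed.

## The synthetic landscape

The generator emulates the *combinatorial structure* of a curated
inventory, not its biology: no recombination landscape, no LD, uniform
random ACGT genome. What it does reproduce, with exact ground truth in a
manifest:

* multiple studies (6) with distinct populations and countries (3);
* heavily skewed category weights A/B/H/S/Y = 0.08/0.07/0.01/0.30/0.54,
  mirroring the 349/334/42/1,392/2,438 split of a real inventory;
* 300 background QTLs with log-uniform lengths in
  [10 kb, min(5 Mb, chrom/5)] — the law is capped so the skewed length
  distribution fits the 4 × 1 Mb toy chromosomes — of which 20% are
  single-marker point loci;
* planted co-location regions of multiplicity 2, 3, 4 and 5 (two QTLs per
  category, intervals equal to the region by construction) plus one planted
  hot pile-up of 120 QTLs, all kept clear of background QTLs by a 25-kb
  exclusion margin so their boundaries are recoverable to the bp;
* 30% of 200 genes planted inside the regions, the rest outside;
* an Erdős–Rényi interaction graph (p = 0.05) over the gene ids with three
  planted hubs wired to ≥ 65 partners (background degrees concentrate near
  10, far from the 60 threshold).

Marker primer pairs (20-mers, 101-bp amplicons) are embedded verbatim into
the genome, so anchoring ground truth is exact at zero mismatches;
uniqueness of every primer and its reverse complement is verified by an
exhaustive genome-wide 20-mer scan (2-bit-packed rolling window), with
regeneration on collision. All QTLs planted in one co-location region share
its flanking marker pair — co-localized QTLs in real inventories share
markers too, and it is what makes 120 co-located amplicons geometrically
possible. The bundle uses `cm_to_bp = 20 kb/cM` so the 1-cM single-marker
window (20 kb) fits 1-Mb chromosomes; the manifest echoes the calibration
and the pipeline reads it back for recovery runs. Everything is keyed to
one RNG seed; identical configs give byte-identical bundles.

Degradation (`perturb`) deletes one marker from a chosen fraction of
two-marker QTLs (forcing the single-marker window path) and/or jitters
interval endpoints by ±`noise_bp`. Jittered rows are rewritten as
pre-anchored coordinates, because per-QTL re-embedding of shared amplicons
cannot be done disjointly; marker-dropping keeps real markers and real
anchoring.

Because background QTLs legitimately overlap each other, incidental
multi-category regions beyond the planted ones are expected under the
default configuration; recovery is therefore measured as 100% *recall* of
planted structures (exact boundaries, multiplicities, counts and flags),
and exact set equality of candidates is asserted on a background-free
configuration. Category-frequency calibration is checked on a
planted-region-free configuration, since planted categories are forced by
construction.

What passing these tests shows: the anchoring, projection, decomposition,
merging, intersection and degree machinery is exact on inputs whose truth
is known. What it does not show: anything about curation quality, marker
reliability, or interval calibration on real inventories — those enter
through the input tables and the `cm_to_bp`/window conventions documented
above.

## Numerical choices and degenerate inputs

* Coordinates are 1-based inclusive everywhere internally (GFF3
  convention); BED converts at the I/O boundary (`bed_start = start − 1`,
  `bed_end = end`). Point loci are honest 1-bp intervals.
* Window half-span rounding: round-half-up, `floor(x + 0.5)`.
* Amplicon midpoint: `(start + end) // 2`; the simulator plants odd-length
  amplicons so midpoints are exact.
* Qtl-id collisions across studies are disambiguated by prefixing the
  study id (aggregated inventories reuse local QTL names).
* Empty inputs are valid: an empty edge list is an empty network, an empty
  region list writes a header-only table, a chromosome without QTLs yields
  no segments.
* A-vs-C genome split is by chromosome-name prefix; unknown prefixes are
  reported under "other", never guessed.
* Region/atlas TSVs round-trip bit-identically (tested), so every number
  in the run report is recomputable from the files.

## Problem sizes used in the checks

The bundled verification uses desk-scale instances chosen to make
exhaustive oracles exact and fast: ≥ 200 random landscapes of ≤ 60 QTLs on
≤ 10-kb chromosomes for the per-bp region oracle (both merge policies, plus
trait-pair co-localization), ≥ 100 random genome/primer instances at 0–2
mismatches for the e-PCR oracle, and the default 4 × 1 Mb synthetic bundle
(448 QTLs, 543 markers, 200 genes) for end-to-end recovery, unperturbed and
under 5-kb endpoint noise.

## Known limitations

* Hamming-only primer matching: no indels, no thermodynamics, no BLAST-style
  seeding — by design, matching classical STS e-PCR.
* The cM→bp conversion is a constant (optionally per-chromosome) factor;
  no recombination-map interpolation, and no meta-analysis shrinking of QTL
  confidence intervals.
* Hot-region calling is a raw count cutoff, not an enrichment statistic.
* GO-slim grouping is a lookup, not an enrichment test; interaction
  networks are consumed, never predicted.
* Reproducing the headline counts of any specific published inventory
  requires that inventory's curated table as input, and depends on its
  (usually unstated) region-merging convention — which is exactly why both
  policies are implemented and reported.
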