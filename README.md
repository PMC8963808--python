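# qtlatlas

A toolkit for building a **quantitative genomic map** from multi-study QTL
inventories, in the style used for *Brassica napus* (rapeseed) agronomic and
disease-related traits. Decades of QTL mapping and GWAS leave hundreds of
loci scattered across papers, each reported against its own linkage map.
`qtlatlas` aligns them on one physical reference assembly and asks the
question breeders care about: *where do QTLs for different kinds of traits —
seed composition, yield, hormones, biotic and abiotic stress — pile up in
the same place?* Such co-localization regions are candidates for pleiotropic
or tightly linked loci, and the genes inside them are candidates for
multi-trait selection.

It is written for researchers doing QTL meta-analysis and candidate-gene
work in crops: a Python library plus a `qtlatlas` command-line tool.

## What it computes

1. **Marker anchoring (e-PCR).** Flanking markers given as STS primer pairs
   (or raw sequences, or known positions) are located on the genome by
   in-silico PCR: forward primer matching one strand within a Hamming
   mismatch budget, reverse-complemented reverse primer downstream, product
   size in a window, both orientations.
2. **Projection.** Two anchored markers span the interval
   `[min(p₁,p₂), max(p₁,p₂)]`; a QTL with a single flanking marker is kept
   and given a 1-cM window centred on the marker, converted at a
   configurable `cm_to_bp` factor (default 425 kb/cM for *B. napus*).
3. **Overlap regions.** A sweep line decomposes each chromosome into
   atomic segments with a constant covering-QTL set; maximal runs of
   adjacent segments carrying ≥ 2 of the five trait categories
   (A/B/H/S/Y = abiotic, biotic, hormone, seed component, yield) become
   overlap regions with per-category distinct-QTL counts and a
   multiplicity of 2–5. *Hot* regions host > 100 distinct QTLs;
   environment/population-specific regions draw all their QTLs from one
   country/population; trait pairs (e.g. oil content × seed yield) can be
   co-localized directly.
4. **Candidate genes and hubs.** Genes intersecting overlap regions are
   nominated (overlap or containment semantics), stratified by region
   multiplicity, and ranked by degree in a gene-interaction network
   (hubs: degree ≥ 60), with optional GO-slim biological-process grouping.
5. **Exports.** TSV/BED tables, Circos karyotype + per-category track
   files, and a machine-readable run report.

A first-class synthetic-data generator produces complete, ground-truthed
input bundles (genome with embedded marker primers, multi-study QTL table,
gene annotation, interaction edge list, manifest), so the entire pipeline
is testable end to end without downloads. See `docs/methods.md` for the
model, conventions and limitations.

## Worked example

```bash
qtlatlas simulate --outdir bundle --seed 42
qtlatlas run \
    --genome bundle/genome.fa --qtls bundle/qtls.tsv \
    --chrom-sizes bundle/chrom_sizes.tsv --catalog bundle/trait_catalog.tsv \
    --genes bundle/genes.gff3 --edges bundle/edges.tsv \
    --go-slim bundle/go_slim.tsv --cm-to-bp 20000 --outdir out
# QTLs kept: 448; regions: 93; report: out/report.json
```

The bundle plants, on four 1-Mb chromosomes, co-location regions of
multiplicity 2–5, one hot pile-up of 120 QTLs, 60 genes inside the regions
and 3 network hubs, plus 300 background QTLs (the `--cm-to-bp 20000`
calibration matches the bundle's toy scale). The run report
(`out/report.json`) then shows, among others:

* 543/543 markers anchored, 448 QTLs projected with 0 rejections
  (273 on the A genome, 175 on C; category counts
  A:27 B:26 H:4 S:154 Y:237);
* 93 overlap regions — 48/31/12/2 of multiplicity 2/3/4/5 — including
  exactly one hot region, `A1 0.60–0.70 Mb` with 120 QTLs (60 S + 60 Y):
  the planted pile-up, recovered to the base pair;
* 167 candidate genes (all 60 planted ones among them) and a 200-node,
  1,183-edge network whose 3 hubs are exactly the planted ones.

All tables in `out/` are plain TSV/BED; `out/circos/` holds the karyotype
and the five category tracks in map order (yield innermost).

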