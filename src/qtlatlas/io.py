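"""Validated readers and writers for the external formats.

Internal coordinates are 1-based inclusive everywhere; BED is converted at
this boundary (BED start = internal start - 1, BED end = internal end).
"""
from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    CATEGORY_CODES,
    GeneRecord,
    GenomeAssembly,
    InteractionNetwork,
    MarkerSpec,
    QtlAtlasError,
    RawQTLRecord,
    TraitCatalog,
)

# ---------------------------------------------------------------- genome ----

def load_chrom_sizes(path, name: str = "assembly") -> GenomeAssembly:
    """Two-column TSV (chrom_id, length in bp); order preserved."""
    chroms: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise QtlAtlasError(f"{path}:{lineno}: expected 2 columns")
            chrom = parts[0].strip()
            if chrom in seen:
                raise QtlAtlasError(f"{path}:{lineno}: duplicate chromosome id {chrom!r}")
            seen.add(chrom)
            try:
                length = int(parts[1])
            except ValueError:
                raise QtlAtlasError(
                    f"{path}:{lineno}: non-integer length {parts[1]!r}"
                ) from None
            chroms.append((chrom, length))
    return GenomeAssembly(name=name, chromosomes=chroms)


def load_genome_fasta(path, assembly: Optional[GenomeAssembly] = None) -> GenomeAssembly:
    """Read FASTA sequences; if ``assembly`` is given its chromosome order and
    declared lengths are kept (and checked), otherwise order/lengths come from
    the FASTA itself."""
    seqs: dict[str, str] = {}
    order: list[tuple[str, int]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
        order.append((rec.id, len(rec.seq)))
    if assembly is None:
        return GenomeAssembly(name=Path(str(path)).stem, chromosomes=order, sequences=seqs)
    return GenomeAssembly(name=assembly.name, chromosomes=list(assembly.chromosomes),
                          sequences=seqs)


def write_genome_fasta(genome: GenomeAssembly, path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(genome.sequence(chrom)), id=chrom, description="")
        for chrom, _ in genome.chromosomes
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# -------------------------------------------------------------- catalogs ----

def load_trait_catalog(path=None) -> TraitCatalog:
    """Trait -> category TSV with header (trait, category). With no path the
    catalog bundled with the package is used."""
    if path is None:
        path = importlib.resources.files("qtlatlas.data") / "trait_catalog.tsv"
    df = pd.read_csv(str(path), sep="\t", dtype=str)
    if not {"trait", "category"}.issubset(df.columns):
        raise QtlAtlasError("trait catalog needs columns (trait, category)")
    return TraitCatalog.from_pairs(zip(df["trait"], df["category"]))


def load_go_slim_vocabulary(path=None) -> list[str]:
    """The GO-slim biological-process class names (one per line)."""
    if path is None:
        path = importlib.resources.files("qtlatlas.data") / "go_slim_classes.txt"
    with open(str(path)) as fh:
        return [line.strip() for line in fh if line.strip()]


def read_go_mapping(path) -> dict[str, str]:
    """Two-column TSV gene_id -> GO-slim class (header optional)."""
    df = pd.read_csv(str(path), sep="\t", dtype=str, header=None, comment="#")
    if df.iloc[0, 0] in ("gene_id", "gene"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# ------------------------------------------------------------- QTL table ----

QTL_TABLE_COLUMNS = [
    "qtl_id", "trait", "study", "population", "country",
    "left_marker", "left_fwd", "left_rev",
    "right_marker", "right_fwd", "right_rev",
    "chrom", "start", "end",
]


@dataclass
class CurationReport:
    n_input: int = 0
    n_kept: int = 0
    dropped: list[tuple[str, str]] = field(default_factory=list)  # (row label, reason)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


def _marker_from_row(row, side: str) -> Optional[MarkerSpec]:
    mid = row.get(f"{side}_marker", "")
    fwd = row.get(f"{side}_fwd", "")
    rev = row.get(f"{side}_rev", "")
    if not mid:
        return None
    if fwd and rev:
        return MarkerSpec(marker_id=mid, kind="primer_pair",
                          forward_primer=fwd, reverse_primer=rev)
    if fwd:
        return MarkerSpec(marker_id=mid, kind="sequence", sequence=fwd)
    return None


def read_qtl_table(path, catalog: TraitCatalog) -> tuple[list[RawQTLRecord], CurationReport]:
    """Parse the delimited multi-study QTL table and apply the curation rules:
    rows with no anchoring information at all are dropped (counted), rows with
    an uncatalogued trait or malformed coordinates are rejected with a reason,
    rows with exactly one flanking marker are kept (projected later through
    the 1-cM window rule). Colliding qtl_ids across studies are disambiguated
    by prefixing the study id."""
    df = pd.read_csv(str(path), sep="\t", dtype=str).fillna("")
    missing = set(QTL_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise QtlAtlasError(f"QTL table missing columns: {sorted(missing)}")
    report = CurationReport(n_input=len(df))
    records: list[RawQTLRecord] = []
    for i, row in df.iterrows():
        label = row["qtl_id"] or f"row{i + 2}"
        trait = row["trait"].strip()
        if trait not in catalog:
            report.dropped.append((label, "uncatalogued trait"))
            continue
        try:
            left = _marker_from_row(row, "left")
            right = _marker_from_row(row, "right")
        except QtlAtlasError as exc:
            report.dropped.append((label, f"bad marker: {exc}"))
            continue
        pre = None
        if row["chrom"]:
            try:
                start, end = int(row["start"]), int(row["end"])
            except ValueError:
                report.dropped.append((label, "malformed coordinates"))
                continue
            if start > end:
                report.dropped.append((label, "malformed coordinates"))
                continue
            pre = (row["chrom"], start, end)
        if left is None and right is None and pre is None:
            report.dropped.append((label, "no anchoring information"))
            continue
        records.append(
            RawQTLRecord(
                qtl_id=label, trait_name=trait, study_id=row["study"],
                population=row["population"], country=row["country"],
                left_marker=left, right_marker=right, preanchored_interval=pre,
            )
        )
    # disambiguate qtl_id collisions across studies
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.qtl_id] = counts.get(rec.qtl_id, 0) + 1
    for rec in records:
        if counts[rec.qtl_id] > 1:
            rec.qtl_id = f"{rec.study_id}:{rec.qtl_id}"
    if len({r.qtl_id for r in records}) != len(records):
        raise QtlAtlasError("qtl_ids not unique even after study prefixing")
    report.n_kept = len(records)
    return records, report


def read_marker_table(path) -> list[MarkerSpec]:
    """Marker table TSV with header (marker_id, fwd, rev[, chrom, pos]); rows
    with primers become primer_pair specs, rows with only chrom/pos become
    position specs."""
    df = pd.read_csv(str(path), sep="\t", dtype=str).fillna("")
    specs = []
    for _, row in df.iterrows():
        if row.get("fwd") and row.get("rev"):
            specs.append(MarkerSpec(row["marker_id"], "primer_pair",
                                    forward_primer=row["fwd"], reverse_primer=row["rev"]))
        elif row.get("chrom") and row.get("pos"):
            specs.append(MarkerSpec(row["marker_id"], "position",
                                    position=(row["chrom"], int(row["pos"]))))
        else:
            raise QtlAtlasError(f"marker {row['marker_id']}: neither primers nor position")
    return specs


# ------------------------------------------------------------ annotation ----

def _genes_from_bed(path) -> list[GeneRecord]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise QtlAtlasError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, s0, e0 = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 and parts[3] not in ("", ".") else f"feature{lineno}"
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
            if s0 >= e0:
                raise QtlAtlasError(f"{path}:{lineno}: empty or inverted BED interval")
            genes.append(GeneRecord(name, chrom, s0 + 1, e0, strand))
    return genes


def _genes_from_gff3(path) -> list[GeneRecord]:
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = feat.attributes.get("ID", [feat.id])[0]
        if feat.start > feat.end:
            raise QtlAtlasError(f"gene {gid}: start > end")
        strand = feat.strand if feat.strand in ("+", "-") else "."
        genes.append(GeneRecord(gid, feat.seqid, feat.start, feat.end, strand))
    return genes


def read_gene_annotation(path, assembly: Optional[GenomeAssembly] = None) -> list[GeneRecord]:
    """GFF3 (gene features) or BED, auto-detected by extension then content.
    Coordinates are normalized to 1-based inclusive. Features on chromosomes
    absent from ``assembly`` (when given) are skipped with a warning."""
    suffix = Path(str(path)).suffix.lower()
    if suffix in (".gff", ".gff3"):
        genes = _genes_from_gff3(path)
    elif suffix == ".bed":
        genes = _genes_from_bed(path)
    else:
        with open(path) as fh:
            head = fh.readline()
        if head.startswith("##gff") or head.count("\t") >= 8:
            genes = _genes_from_gff3(path)
        else:
            genes = _genes_from_bed(path)
    if assembly is not None:
        known = set(assembly.lengths)
        skipped = [g for g in genes if g.chrom_id not in known]
        if skipped:
            warnings.warn(
                f"{len(skipped)} gene(s) on chromosomes absent from the assembly were skipped",
                stacklevel=2,
            )
            genes = [g for g in genes if g.chrom_id in known]
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise QtlAtlasError("duplicate gene ids in annotation")
    return genes


def write_genes_gff3(genes: Iterable[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom_id}\tqtlatlas\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


# -------------------------------------------------------------- networks ----

def read_edge_list(path) -> InteractionNetwork:
    """Two-column delimited node pairs -> deduplicated undirected graph;
    self-loops dropped (counted). An empty file yields an empty network."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise QtlAtlasError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and parts[0].lower() in ("node1", "gene1", "source"):
                continue
            pairs.append((parts[0], parts[1]))
    return InteractionNetwork.from_edges(pairs)


def write_edge_list(network: InteractionNetwork, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in network.graph.edges):
            fh.write(f"{a}\t{b}\n")


# --------------------------------------------------------------- regions ----

REGION_TSV_COLUMNS = [
    "region_id", "chrom", "start", "end", "n_qtls", "multiplicity", "categories",
    "n_A", "n_B", "n_H", "n_S", "n_Y",
    "hot", "environment_specific", "population_specific", "specific_value",
    "qtl_ids",
]


def write_regions(regions, path, format: str = "tsv") -> None:
    """Write overlap regions as TSV (1-based inclusive, full bookkeeping
    columns) or BED (0-based half-open). An empty list yields a header-only
    TSV / empty BED."""
    from .regions import OverlapRegion  # local import to avoid a cycle

    if format == "tsv":
        rows = []
        for r in regions:
            rows.append({
                "region_id": r.region_id, "chrom": r.chrom_id,
                "start": r.start, "end": r.end,
                "n_qtls": r.n_qtls, "multiplicity": r.multiplicity,
                "categories": ",".join(sorted(r.categories)),
                **{f"n_{c}": r.per_category_counts.get(c, 0) for c in CATEGORY_CODES},
                "hot": int(r.hot),
                "environment_specific": int(r.environment_specific),
                "population_specific": int(r.population_specific),
                "specific_value": r.specific_value or "",
                "qtl_ids": ",".join(sorted(r.qtl_ids)),
            })
        pd.DataFrame(rows, columns=REGION_TSV_COLUMNS).to_csv(
            str(path), sep="\t", index=False
        )
    elif format == "bed":
        with open(path, "w") as fh:
            for r in regions:
                fh.write(
                    f"{r.chrom_id}\t{r.start - 1}\t{r.end}\t{r.region_id}\t{r.multiplicity}\n"
                )
    else:
        raise QtlAtlasError(f"unknown region format: {format!r}")


def read_regions_tsv(path):
    """Inverse of :func:`write_regions` (TSV flavor); round-trips every field."""
    from .regions import OverlapRegion

    df = pd.read_csv(str(path), sep="\t", dtype=str).fillna("")
    regions = []
    for _, row in df.iterrows():
        counts = {c: int(row[f"n_{c}"]) for c in CATEGORY_CODES}
        regions.append(OverlapRegion(
            region_id=row["region_id"], chrom_id=row["chrom"],
            start=int(row["start"]), end=int(row["end"]),
            qtl_ids=frozenset(row["qtl_ids"].split(",")) if row["qtl_ids"] else frozenset(),
            per_category_counts=counts,
            hot=bool(int(row["hot"])),
            environment_specific=bool(int(row["environment_specific"])),
            population_specific=bool(int(row["population_specific"])),
            specific_value=row["specific_value"] or None,
        ))
    return regions


# ----------------------------------------------------------------- atlas ----

ATLAS_TSV_COLUMNS = [
    "qtl_id", "trait", "category", "study", "population", "country",
    "chrom", "start", "end", "provenance",
]


def write_atlas_tsv(qtls, path) -> None:
    rows = [{
        "qtl_id": q.qtl_id, "trait": q.trait_name, "category": q.category,
        "study": q.study_id, "population": q.population, "country": q.country,
        "chrom": q.chrom_id, "start": q.start, "end": q.end,
        "provenance": q.provenance,
    } for q in qtls]
    pd.DataFrame(rows, columns=ATLAS_TSV_COLUMNS).to_csv(str(path), sep="\t", index=False)


def read_atlas_tsv(path):
    from .model import PhysicalQTL

    df = pd.read_csv(str(path), sep="\t", dtype=str).fillna("")
    return [
        PhysicalQTL(
            chrom_id=row["chrom"], start=int(row["start"]), end=int(row["end"]),
            qtl_id=row["qtl_id"], trait_name=row["trait"], category=row["category"],
            study_id=row["study"], population=row["population"], country=row["country"],
            provenance=row["provenance"],
        )
        for _, row in df.iterrows()
    ]


def write_marker_hits_tsv(marker_map: dict[str, tuple[str, int]], path) -> None:
    with open(path, "w") as fh:
        fh.write("marker_id\tchrom\tpos\n")
        for mid in sorted(marker_map):
            chrom, pos = marker_map[mid]
            fh.write(f"{mid}\t{chrom}\t{pos}\n")


def write_candidates_tsv(candidates, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tregions\tmax_multiplicity\tcategories\n")
        for c in candidates:
            fh.write(
                f"{c.gene_id}\t{c.chrom_id}\t{c.start}\t{c.end}\t"
                f"{','.join(sorted(c.region_ids))}\t{c.max_multiplicity}\t"
                f"{','.join(sorted(c.categories_union))}\n"
            )


def write_hubs_tsv(nodes, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tdegree\tgo_slim_class\tis_hub\n")
        for n in sorted(nodes, key=lambda n: (-n.degree, n.gene_id)):
            fh.write(f"{n.gene_id}\t{n.degree}\t{n.go_slim_class or ''}\t{int(n.is_hub)}\n")
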