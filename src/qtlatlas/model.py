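"""Core domain types for the quantitative genomic map.

All genomic coordinates in this package are 1-based inclusive (the GFF3
convention). BED input/output converts at the I/O boundary only.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

#: The five trait categories: abiotic factor, biotic factor, hormone level,
#: seed component, yield-related.
CATEGORY_CODES: tuple[str, ...] = ("A", "B", "H", "S", "Y")

CATEGORY_LABELS: dict[str, str] = {
    "A": "abiotic factor",
    "B": "biotic factor",
    "H": "hormone level",
    "S": "seed component",
    "Y": "yield related",
}

#: IUPAC nucleotide alphabet accepted in primers and marker sequences.
IUPAC_LETTERS = frozenset("ACGTRYSWKMBDHVN")

MIN_PRIMER_LENGTH = 10
MIN_MARKER_SEQUENCE_LENGTH = 15


class QtlAtlasError(ValueError):
    """Base class for domain validation errors."""


@dataclass
class GenomeAssembly:
    """A reference assembly: ordered chromosomes with lengths, optional sequences.

    ``chromosomes`` preserves input order; ``sequences`` (upper-case strings
    keyed by chromosome id) are only needed for marker anchoring.
    """

    name: str
    chromosomes: list[tuple[str, int]]
    sequences: Optional[dict[str, str]] = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for chrom, length in self.chromosomes:
            if chrom in seen:
                raise QtlAtlasError(f"duplicate chromosome id: {chrom!r}")
            seen.add(chrom)
            if int(length) < 1:
                raise QtlAtlasError(f"chromosome {chrom!r} has length {length} < 1")
        if self.sequences is not None:
            for chrom, length in self.chromosomes:
                if chrom in self.sequences and len(self.sequences[chrom]) != length:
                    raise QtlAtlasError(
                        f"sequence length for {chrom!r} "
                        f"({len(self.sequences[chrom])}) != declared {length}"
                    )

    @property
    def chrom_ids(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return {c: l for c, l in self.chromosomes}

    def length(self, chrom_id: str) -> int:
        try:
            return self.lengths[chrom_id]
        except KeyError:
            raise QtlAtlasError(f"unknown chromosome: {chrom_id!r}") from None

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def chrom_order(self) -> dict[str, int]:
        return {c: i for i, (c, _) in enumerate(self.chromosomes)}

    def sequence(self, chrom_id: str) -> str:
        if self.sequences is None or chrom_id not in self.sequences:
            raise QtlAtlasError(f"no sequence loaded for chromosome {chrom_id!r}")
        return self.sequences[chrom_id]


def _check_dna(text: str, what: str) -> None:
    bad = set(text.upper()) - IUPAC_LETTERS
    if bad:
        raise QtlAtlasError(f"{what} contains non-IUPAC letters: {sorted(bad)}")


@dataclass(frozen=True)
class MarkerSpec:
    """How one flanking marker can be located: a primer pair (STS), a raw
    sequence, or a known physical position."""

    marker_id: str
    kind: str  # primer_pair | sequence | position
    forward_primer: Optional[str] = None
    reverse_primer: Optional[str] = None
    sequence: Optional[str] = None
    position: Optional[tuple[str, int]] = None

    def __post_init__(self) -> None:
        if self.kind == "primer_pair":
            if not self.forward_primer or not self.reverse_primer:
                raise QtlAtlasError(f"marker {self.marker_id}: primer_pair needs both primers")
            for p, side in ((self.forward_primer, "forward"), (self.reverse_primer, "reverse")):
                _check_dna(p, f"marker {self.marker_id} {side} primer")
                if len(p) < MIN_PRIMER_LENGTH:
                    raise QtlAtlasError(
                        f"marker {self.marker_id}: {side} primer shorter than {MIN_PRIMER_LENGTH} nt"
                    )
        elif self.kind == "sequence":
            if not self.sequence:
                raise QtlAtlasError(f"marker {self.marker_id}: sequence kind needs a sequence")
            _check_dna(self.sequence, f"marker {self.marker_id} sequence")
        elif self.kind == "position":
            if self.position is None:
                raise QtlAtlasError(f"marker {self.marker_id}: position kind needs a position")
        else:
            raise QtlAtlasError(f"marker {self.marker_id}: unknown kind {self.kind!r}")


@dataclass
class RawQTLRecord:
    """One curated QTL/GWAS row before physical projection."""

    qtl_id: str
    trait_name: str
    study_id: str
    population: str
    country: str
    left_marker: Optional[MarkerSpec] = None
    right_marker: Optional[MarkerSpec] = None
    preanchored_interval: Optional[tuple[str, int, int]] = None

    def __post_init__(self) -> None:
        if (
            self.left_marker is None
            and self.right_marker is None
            and self.preanchored_interval is None
        ):
            raise QtlAtlasError(f"QTL {self.qtl_id}: no anchoring information")

    @property
    def markers(self) -> list[MarkerSpec]:
        return [m for m in (self.left_marker, self.right_marker) if m is not None]


@dataclass(frozen=True, order=True)
class PhysicalQTL:
    """A QTL projected onto the physical map (1-based inclusive interval)."""

    chrom_id: str
    start: int
    end: int
    qtl_id: str
    trait_name: str
    category: str
    study_id: str
    population: str
    country: str
    provenance: str  # two_markers | one_marker_window | preanchored

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise QtlAtlasError(
                f"QTL {self.qtl_id}: invalid interval [{self.start}, {self.end}]"
            )
        if self.category not in CATEGORY_CODES:
            raise QtlAtlasError(f"QTL {self.qtl_id}: invalid category {self.category!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise QtlAtlasError(f"gene {self.gene_id}: start > end")
        if self.strand not in ("+", "-", "."):
            raise QtlAtlasError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class InteractionNetwork:
    """Undirected gene-interaction graph (no self-loops, no duplicate edges)."""

    graph: nx.Graph
    n_self_loops_dropped: int = 0

    @classmethod
    def from_edges(cls, pairs) -> "InteractionNetwork":
        g = nx.Graph()
        dropped = 0
        for a, b in pairs:
            a, b = str(a), str(b)
            if a == b:
                dropped += 1
                continue
            g.add_edge(a, b)
        return cls(graph=g, n_self_loops_dropped=dropped)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class TraitCatalog:
    """Case-insensitive trait name -> category code lookup."""

    mapping: dict[str, str]  # lower-cased trait -> code

    @classmethod
    def from_pairs(cls, pairs) -> "TraitCatalog":
        mapping: dict[str, str] = {}
        for trait, code in pairs:
            key = str(trait).strip().lower()
            code = str(code).strip().upper()
            if code not in CATEGORY_CODES:
                raise QtlAtlasError(f"trait {trait!r}: unknown category code {code!r}")
            if key in mapping and mapping[key] != code:
                raise QtlAtlasError(f"trait {trait!r} mapped to two categories")
            mapping[key] = code
        return cls(mapping=mapping)

    def category(self, trait_name: str) -> str:
        try:
            return self.mapping[trait_name.strip().lower()]
        except KeyError:
            raise QtlAtlasError(f"uncatalogued trait: {trait_name!r}") from None

    def __contains__(self, trait_name: str) -> bool:
        return trait_name.strip().lower() in self.mapping

    @property
    def traits(self) -> list[str]:
        return sorted(self.mapping)


@dataclass
class RunConfig:
    """Tunable thresholds of the pipeline, with field-standard defaults.

    ``cm_to_bp`` converts the 1-cM single-marker window to base pairs
    (425 kb/cM ~ 850 Mb over ~2,000 cM for B. napus). ``hot_threshold`` is a
    strict lower bound (a hot region hosts *more than* this many distinct
    QTLs); ``hub_degree_threshold`` is inclusive (degree >= threshold).
    """

    window_cM: float = 1.0
    cm_to_bp: float = 425_000.0
    window_anchor: str = "center"  # center | right
    min_categories: int = 2
    hot_threshold: int = 100
    hub_degree_threshold: int = 60
    gene_intersection_mode: str = "overlap"  # overlap | contained
    region_merge_policy: str = "constant_category_set"  # or constant_multiplicity
    specificity_min_qtls: int = 2
    max_mismatch: int = 1
    size_min: int = 50
    size_max: int = 5000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.window_cM <= 0 or self.cm_to_bp <= 0:
            raise QtlAtlasError("window_cM and cm_to_bp must be positive")
        for name in ("min_categories", "hot_threshold", "hub_degree_threshold",
                     "specificity_min_qtls"):
            if getattr(self, name) <= 0:
                raise QtlAtlasError(f"{name} must be positive")
        if self.window_anchor not in ("center", "right"):
            raise QtlAtlasError(f"window_anchor: {self.window_anchor!r}")
        if self.gene_intersection_mode not in ("overlap", "contained"):
            raise QtlAtlasError(f"gene_intersection_mode: {self.gene_intersection_mode!r}")
        if self.region_merge_policy not in ("constant_category_set", "constant_multiplicity"):
            raise QtlAtlasError(f"region_merge_policy: {self.region_merge_policy!r}")
        if self.max_mismatch < 0 or self.size_min > self.size_max:
            raise QtlAtlasError("invalid e-PCR parameters")
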