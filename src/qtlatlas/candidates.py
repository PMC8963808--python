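"""Candidate-gene nomination and interaction-network analysis.

Genes intersecting overlap regions are candidates for the co-localized
traits. ``overlap`` mode requires >= 1 shared bp, ``contained`` requires the
gene to lie fully inside a region. Network hubs are nodes with degree >=
the (inclusive) hub threshold, optionally grouped by GO-slim biological
process class.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from intervaltree import IntervalTree

from .io import load_go_slim_vocabulary
from .model import GeneRecord, InteractionNetwork, QtlAtlasError
from .regions import OverlapRegion


@dataclass(frozen=True)
class CandidateGene:
    gene_id: str
    chrom_id: str
    start: int
    end: int
    region_ids: frozenset[str]
    max_multiplicity: int
    categories_union: frozenset[str]


@dataclass
class NetworkNode:
    gene_id: str
    degree: int
    go_slim_class: Optional[str] = None
    is_hub: bool = False


def intersect_genes(
    genes: Iterable[GeneRecord],
    regions: Iterable[OverlapRegion],
    mode: str = "overlap",
) -> list[CandidateGene]:
    """Nominate genes intersecting overlap regions, sorted by
    (chrom, start, gene_id). Genes on chromosomes without regions are simply
    not candidates."""
    if mode not in ("overlap", "contained"):
        raise QtlAtlasError(f"unknown gene intersection mode: {mode!r}")
    trees: dict[str, IntervalTree] = {}
    for r in regions:
        trees.setdefault(r.chrom_id, IntervalTree()).addi(r.start, r.end + 1, r)
    out: list[CandidateGene] = []
    for g in genes:
        tree = trees.get(g.chrom_id)
        if tree is None:
            continue
        hits = [iv.data for iv in tree.overlap(g.start, g.end + 1)]
        if mode == "contained":
            hits = [r for r in hits if r.start <= g.start and g.end <= r.end]
        if not hits:
            continue
        out.append(CandidateGene(
            gene_id=g.gene_id, chrom_id=g.chrom_id, start=g.start, end=g.end,
            region_ids=frozenset(r.region_id for r in hits),
            max_multiplicity=max(r.multiplicity for r in hits),
            categories_union=frozenset().union(*(r.categories for r in hits)),
        ))
    out.sort(key=lambda c: (c.chrom_id, c.start, c.gene_id))
    return out


def stratify_candidates(candidates: Iterable[CandidateGene]) -> dict[str, dict]:
    """Partition candidates by the highest multiplicity among their regions,
    and count per chromosome."""
    by_mult: dict[int, int] = {}
    by_chrom: dict[str, int] = {}
    n = 0
    for c in candidates:
        n += 1
        by_mult[c.max_multiplicity] = by_mult.get(c.max_multiplicity, 0) + 1
        by_chrom[c.chrom_id] = by_chrom.get(c.chrom_id, 0) + 1
    return {"total": n, "by_multiplicity": by_mult, "by_chromosome": by_chrom}


def degree_analysis(network: InteractionNetwork) -> list[NetworkNode]:
    """One node per gene with its degree (number of interaction partners)."""
    return [
        NetworkNode(gene_id=str(node), degree=int(deg))
        for node, deg in sorted(network.graph.degree)
    ]


def select_hubs(nodes: Iterable[NetworkNode], threshold: int = 60) -> list[NetworkNode]:
    """Hub genes: degree >= threshold (inclusive). Flags are set on the input
    nodes; the hub subset is returned."""
    hubs = []
    for n in nodes:
        n.is_hub = n.degree >= threshold
        if n.is_hub:
            hubs.append(n)
    return hubs


def assign_go_slim(
    nodes: Iterable[NetworkNode],
    mapping: dict[str, str],
    vocabulary: Optional[list[str]] = None,
) -> list[NetworkNode]:
    """Attach a GO-slim biological-process class to each node; genes absent
    from the mapping are classified as "Others". Mapped class names must come
    from the 16-name vocabulary."""
    vocab = set(vocabulary if vocabulary is not None else load_go_slim_vocabulary())
    nodes = list(nodes)
    for n in nodes:
        cls = mapping.get(n.gene_id)
        if cls is None:
            n.go_slim_class = "Others"
        else:
            if cls not in vocab:
                raise QtlAtlasError(f"unknown GO-slim class: {cls!r}")
            n.go_slim_class = cls
    return nodes
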