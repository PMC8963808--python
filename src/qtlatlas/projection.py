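"""Projection of curated QTL records onto the physical map.

Two anchored flanking markers span the interval between their positions. A
single anchored marker gets a 1-cM window (converted at ``cm_to_bp``); by
default the window is centered on the marker (+-0.5 cM), the alternative
reading (marker to marker + 1 cM) is available via ``window_anchor="right"``.
Pre-anchored records pass through after bounds clamping.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from .model import (
    CATEGORY_CODES,
    GenomeAssembly,
    PhysicalQTL,
    QtlAtlasError,
    RawQTLRecord,
    TraitCatalog,
)


@dataclass
class ProjectionCalibration:
    """cM -> bp conversion for the single-marker window rule.

    ``cm_to_bp`` may be overridden per chromosome. Rounding of the window
    half-span is round-half-up, frozen.
    """

    cm_to_bp: float = 425_000.0
    window_cM: float = 1.0
    window_anchor: str = "center"  # center | right
    per_chrom: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.cm_to_bp <= 0 or self.window_cM <= 0:
            raise QtlAtlasError("cm_to_bp and window_cM must be positive")
        if self.window_anchor not in ("center", "right"):
            raise QtlAtlasError(f"window_anchor: {self.window_anchor!r}")

    def factor(self, chrom_id: str) -> float:
        if self.per_chrom and chrom_id in self.per_chrom:
            return self.per_chrom[chrom_id]
        return self.cm_to_bp


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class Rejection:
    qtl_id: str
    reason: str


def categorize_trait(trait_name: str, catalog: TraitCatalog) -> str:
    """Exact (case-normalized) catalog lookup; unknown traits raise."""
    return catalog.category(trait_name)


def project_qtl(
    raw: RawQTLRecord,
    marker_map: dict[str, tuple[str, int]],
    calibration: ProjectionCalibration,
    catalog: TraitCatalog,
    assembly: GenomeAssembly,
) -> Union[PhysicalQTL, Rejection]:
    """Project one record; anchoring failures yield a :class:`Rejection`."""
    try:
        category = categorize_trait(raw.trait_name, catalog)
    except QtlAtlasError:
        return Rejection(raw.qtl_id, "uncatalogued trait")

    anchored = [
        marker_map[m.marker_id] for m in raw.markers if m.marker_id in marker_map
    ]
    if len(anchored) >= 2:
        (c1, p1), (c2, p2) = anchored[0], anchored[1]
        if c1 != c2:
            return Rejection(raw.qtl_id, "markers on different chromosomes")
        chrom, start, end = c1, min(p1, p2), max(p1, p2)
        provenance = "two_markers"
    elif len(anchored) == 1:
        chrom, pos = anchored[0]
        width = calibration.window_cM * calibration.factor(chrom)
        if calibration.window_anchor == "center":
            half = _round_half_up(width / 2)
            start, end = pos - half, pos + half
        else:
            start, end = pos, pos + _round_half_up(width)
        provenance = "one_marker_window"
    elif raw.preanchored_interval is not None:
        chrom, start, end = raw.preanchored_interval
        provenance = "preanchored"
    else:
        return Rejection(raw.qtl_id, "no anchorable marker")

    if chrom not in assembly.lengths:
        return Rejection(raw.qtl_id, f"unknown chromosome {chrom!r}")
    length = assembly.length(chrom)
    start, end = max(1, start), min(length, end)
    if start > end:
        return Rejection(raw.qtl_id, "interval outside chromosome")
    return PhysicalQTL(
        chrom_id=chrom, start=start, end=end, qtl_id=raw.qtl_id,
        trait_name=raw.trait_name, category=category, study_id=raw.study_id,
        population=raw.population, country=raw.country, provenance=provenance,
    )


@dataclass
class QTLAtlas:
    """The quantitative genomic map: all projected QTLs on one assembly,
    canonically sorted by (chromosome order, start, end, qtl_id)."""

    assembly: GenomeAssembly
    qtls: list[PhysicalQTL]
    by_chrom: dict[str, list[PhysicalQTL]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        order = self.assembly.chrom_order()
        self.qtls = sorted(
            self.qtls, key=lambda q: (order[q.chrom_id], q.start, q.end, q.qtl_id)
        )
        self.by_chrom = {}
        for q in self.qtls:
            if q.end > self.assembly.length(q.chrom_id):
                raise QtlAtlasError(f"QTL {q.qtl_id} exceeds chromosome bounds")
            self.by_chrom.setdefault(q.chrom_id, []).append(q)

    def by_id(self) -> dict[str, PhysicalQTL]:
        return {q.qtl_id: q for q in self.qtls}

    def qtls_for_trait(self, trait_name: str) -> list[PhysicalQTL]:
        key = trait_name.strip().lower()
        return [q for q in self.qtls if q.trait_name.strip().lower() == key]


@dataclass
class AtlasSummary:
    total: int
    per_chromosome: dict[str, int]
    per_category: dict[str, int]
    per_genome: dict[str, int]  # A / C / other, by chromosome-name prefix
    rejections: list[Rejection]

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "per_chromosome": dict(self.per_chromosome),
            "per_category": dict(self.per_category),
            "per_genome": dict(self.per_genome),
            "n_rejected": len(self.rejections),
            "rejections": [(r.qtl_id, r.reason) for r in self.rejections],
        }


def build_atlas(
    records: Iterable[RawQTLRecord],
    marker_map: dict[str, tuple[str, int]],
    calibration: ProjectionCalibration,
    catalog: TraitCatalog,
    assembly: GenomeAssembly,
) -> tuple[QTLAtlas, AtlasSummary]:
    """Project every record and assemble the atlas with its summary counts
    (total, per chromosome, per category, per A/C genome, rejections)."""
    kept: list[PhysicalQTL] = []
    rejections: list[Rejection] = []
    for raw in records:
        out = project_qtl(raw, marker_map, calibration, catalog, assembly)
        if isinstance(out, Rejection):
            rejections.append(out)
        else:
            kept.append(out)
    atlas = QTLAtlas(assembly=assembly, qtls=kept)
    per_chrom = {c: 0 for c in assembly.chrom_ids}
    per_cat = {c: 0 for c in CATEGORY_CODES}
    per_genome = {"A": 0, "C": 0, "other": 0}
    for q in atlas.qtls:
        per_chrom[q.chrom_id] += 1
        per_cat[q.category] += 1
        prefix = q.chrom_id[:1].upper()
        per_genome[prefix if prefix in ("A", "C") else "other"] += 1
    summary = AtlasSummary(
        total=len(atlas.qtls), per_chromosome=per_chrom, per_category=per_cat,
        per_genome=per_genome, rejections=rejections,
    )
    return atlas, summary
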