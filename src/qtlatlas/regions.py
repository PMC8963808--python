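"""Interval decomposition and multi-trait overlap-region calling.

A chromosome is decomposed by sweep line into maximal *atomic segments* with
a constant set of covering QTLs. Overlap regions are maximal runs of
bp-adjacent atomic segments that qualify (>= ``min_categories`` distinct
trait categories) and are homogeneous under the merge policy:

* ``constant_category_set`` (default): a region ends where the *set* of
  categories present changes;
* ``constant_multiplicity``: adjacency only requires an equal *number* of
  categories.

A QTL touching several regions is counted once in each of them; within one
region a QTL crossing several atomic segments counts once.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import CATEGORY_CODES, PhysicalQTL, QtlAtlasError, RunConfig, TraitCatalog
from .projection import QTLAtlas


@dataclass(frozen=True)
class AtomicSegment:
    chrom_id: str
    start: int
    end: int
    qtl_ids: frozenset[str]
    categories: frozenset[str]

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class OverlapRegion:
    """A maximal genomic interval hosting QTLs of >= 2 trait categories."""

    region_id: str
    chrom_id: str
    start: int
    end: int
    qtl_ids: frozenset[str]
    per_category_counts: dict[str, int]
    hot: bool = False
    environment_specific: bool = False
    population_specific: bool = False
    specific_value: Optional[str] = None

    @property
    def n_qtls(self) -> int:
        return len(self.qtl_ids)

    @property
    def categories(self) -> frozenset[str]:
        return frozenset(c for c, n in self.per_category_counts.items() if n > 0)

    @property
    def multiplicity(self) -> int:
        return len(self.categories)


@dataclass
class RegionSummary:
    total: int
    by_multiplicity: dict[int, int]
    per_chromosome: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "by_multiplicity": {str(k): v for k, v in sorted(self.by_multiplicity.items())},
            "per_chromosome": dict(self.per_chromosome),
        }


def decompose(atlas: QTLAtlas, chrom_id: str) -> list[AtomicSegment]:
    """Sweep-line decomposition of one chromosome: disjoint, sorted maximal
    segments with constant covering QTL set; uncovered stretches are omitted.
    Every covered bp belongs to exactly one segment."""
    if chrom_id not in atlas.assembly.lengths:
        raise QtlAtlasError(f"unknown chromosome: {chrom_id!r}")
    qtls = atlas.by_chrom.get(chrom_id, [])
    if not qtls:
        return []
    starts: dict[int, list[PhysicalQTL]] = {}
    ends: dict[int, list[PhysicalQTL]] = {}
    for q in qtls:
        starts.setdefault(q.start, []).append(q)
        ends.setdefault(q.end + 1, []).append(q)
    points = sorted(set(starts) | set(ends))
    active: set[PhysicalQTL] = set()
    segments: list[AtomicSegment] = []
    for i, p in enumerate(points):
        for q in ends.get(p, ()):
            active.discard(q)
        for q in starts.get(p, ()):
            active.add(q)
        if active and i + 1 < len(points):
            segments.append(AtomicSegment(
                chrom_id=chrom_id, start=p, end=points[i + 1] - 1,
                qtl_ids=frozenset(q.qtl_id for q in active),
                categories=frozenset(q.category for q in active),
            ))
    return segments


def _merge_runs(
    segments: list[AtomicSegment],
    min_categories: int,
    policy: str,
) -> list[list[AtomicSegment]]:
    """Group qualifying segments into maximal bp-adjacent homogeneous runs."""
    def key(seg: AtomicSegment):
        return seg.categories if policy == "constant_category_set" else len(seg.categories)

    runs: list[list[AtomicSegment]] = []
    current: list[AtomicSegment] = []
    for seg in segments:
        if len(seg.categories) < min_categories:
            if current:
                runs.append(current)
                current = []
            continue
        if current and seg.start == current[-1].end + 1 and key(seg) == key(current[-1]):
            current.append(seg)
        else:
            if current:
                runs.append(current)
            current = [seg]
    if current:
        runs.append(current)
    return runs


def _region_from_run(run: list[AtomicSegment], qtl_index: dict[str, PhysicalQTL]) -> OverlapRegion:
    qtl_ids = frozenset().union(*(seg.qtl_ids for seg in run))
    counts = {c: 0 for c in CATEGORY_CODES}
    for qid in qtl_ids:
        counts[qtl_index[qid].category] += 1
    return OverlapRegion(
        region_id="", chrom_id=run[0].chrom_id, start=run[0].start, end=run[-1].end,
        qtl_ids=qtl_ids, per_category_counts=counts,
    )


def call_overlap_regions(
    atlas: QTLAtlas, config: Optional[RunConfig] = None
) -> tuple[list[OverlapRegion], RegionSummary]:
    """Call all overlap regions on the atlas under the configured merge
    policy; per-category counts are over *distinct* QTLs. Regions are sorted
    by (chromosome order, start) and numbered R0001, R0002, ..."""
    config = config or RunConfig()
    qtl_index = atlas.by_id()
    regions: list[OverlapRegion] = []
    for chrom in atlas.assembly.chrom_ids:
        segments = decompose(atlas, chrom)
        for run in _merge_runs(segments, config.min_categories, config.region_merge_policy):
            regions.append(_region_from_run(run, qtl_index))
    for i, r in enumerate(regions, 1):
        r.region_id = f"R{i:04d}"
    return regions, summarize(regions, atlas)


def detect_hot_regions(regions: Iterable[OverlapRegion], hot_threshold: int = 100) -> list[OverlapRegion]:
    """Flag regions hosting strictly more than ``hot_threshold`` distinct
    QTLs; returns the input list with flags set."""
    regions = list(regions)
    for r in regions:
        r.hot = r.n_qtls > hot_threshold
    return regions


def specificity_scan(
    regions: Iterable[OverlapRegion],
    atlas: QTLAtlas,
    field: str = "country",
    min_qtls: int = 2,
) -> list[OverlapRegion]:
    """Flag regions whose covering QTLs all share one country (environment-
    specific) or one population (population-specific), provided the region
    hosts at least ``min_qtls`` QTLs."""
    if field not in ("country", "population"):
        raise QtlAtlasError(f"unknown specificity field: {field!r}")
    qtl_index = atlas.by_id()
    flag = "environment_specific" if field == "country" else "population_specific"
    regions = list(regions)
    for r in regions:
        values = {getattr(qtl_index[qid], field) for qid in r.qtl_ids}
        if len(values) == 1 and r.n_qtls >= min_qtls:
            setattr(r, flag, True)
            r.specific_value = next(iter(values))
        else:
            setattr(r, flag, False)
    return regions


@dataclass(frozen=True)
class ColocRegion:
    """A maximal interval where QTLs of two named traits co-localize."""

    chrom_id: str
    start: int
    end: int
    qtl_ids: frozenset[str]


def trait_pair_colocalization(
    atlas: QTLAtlas, trait_a: str, trait_b: str, catalog: TraitCatalog
) -> list[ColocRegion]:
    """Maximal intervals where every bp is covered by >= 1 QTL of each of the
    two traits (e.g. oil content x seed yield). Runs are merged purely on
    joint presence."""
    for t in (trait_a, trait_b):
        if t not in catalog:
            raise QtlAtlasError(f"uncatalogued trait: {t!r}")
    norm = lambda t: t.strip().lower()
    wanted = {norm(trait_a), norm(trait_b)}
    sub = [q for q in atlas.qtls if norm(q.trait_name) in wanted]
    sub_atlas = QTLAtlas(assembly=atlas.assembly, qtls=sub)
    trait_of = {q.qtl_id: norm(q.trait_name) for q in sub}
    out: list[ColocRegion] = []
    for chrom in atlas.assembly.chrom_ids:
        run: list[AtomicSegment] = []
        for seg in decompose(sub_atlas, chrom):
            both = {trait_of[qid] for qid in seg.qtl_ids} == wanted
            if both and run and seg.start == run[-1].end + 1:
                run.append(seg)
            else:
                if run:
                    out.append(_coloc_from_run(run))
                run = [seg] if both else []
        if run:
            out.append(_coloc_from_run(run))
    return out


def _coloc_from_run(run: list[AtomicSegment]) -> ColocRegion:
    return ColocRegion(
        chrom_id=run[0].chrom_id, start=run[0].start, end=run[-1].end,
        qtl_ids=frozenset().union(*(seg.qtl_ids for seg in run)),
    )


def summarize(regions: Iterable[OverlapRegion], atlas: Optional[QTLAtlas] = None) -> RegionSummary:
    """Counts by multiplicity and by chromosome; totals consistent by
    construction."""
    regions = list(regions)
    by_mult: dict[int, int] = {}
    per_chrom: dict[str, int] = {}
    if atlas is not None:
        per_chrom = {c: 0 for c in atlas.assembly.chrom_ids}
    for r in regions:
        by_mult[r.multiplicity] = by_mult.get(r.multiplicity, 0) + 1
        per_chrom[r.chrom_id] = per_chrom.get(r.chrom_id, 0) + 1
    return RegionSummary(total=len(regions), by_multiplicity=by_mult, per_chromosome=per_chrom)


def covered_length(atlas: QTLAtlas) -> int:
    """Total bp covered by >= 1 QTL (independent interval-union computation)."""
    total = 0
    for chrom in atlas.assembly.chrom_ids:
        ivs = sorted((q.start, q.end) for q in atlas.by_chrom.get(chrom, []))
        cur_s = cur_e = None
        for s, e in ivs:
            if cur_e is None or s > cur_e + 1:
                if cur_e is not None:
                    total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s + 1
    return total


def format_mb(start: int, end: int) -> str:
    """Display helper: Mb with 2 decimals, the field's usual region notation
    (short regions may print as e.g. '2.31-2.31 Mb')."""
    return f"{start / 1e6:.2f}-{end / 1e6:.2f} Mb"
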