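"""Sweep-line decomposition, overlap-region calling and the per-bp oracle."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from qtlatlas import (
    QtlAtlasError,
    RunConfig,
    call_overlap_regions,
    decompose,
    detect_hot_regions,
    specificity_scan,
    summarize,
    trait_pair_colocalization,
)
from qtlatlas.regions import covered_length

from conftest import make_atlas, make_qtl, random_landscape
from oracles import perbp_colocalization, perbp_regions


def test_decompose_hand_worked_example():
    atlas = make_atlas([make_qtl("q1", "A1", 100, 200, "S"),
                        make_qtl("q2", "A1", 150, 300, "Y")])
    segs = decompose(atlas, "A1")
    assert [(s.start, s.end, set(s.qtl_ids)) for s in segs] == [
        (100, 149, {"q1"}), (150, 200, {"q1", "q2"}), (201, 300, {"q2"}),
    ]
    assert segs[1].categories == {"S", "Y"}


def test_decompose_point_interval():
    atlas = make_atlas([make_qtl("q1", "A1", 5, 5)])
    (seg,) = decompose(atlas, "A1")
    assert (seg.start, seg.end) == (5, 5)


def test_decompose_unknown_chromosome_errors():
    atlas = make_atlas([make_qtl("q1", "A1", 5, 5)])
    with pytest.raises(QtlAtlasError, match="unknown chromosome"):
        decompose(atlas, "Z9")


def test_decompose_matches_per_base_tally():
    rng = np.random.default_rng(23)
    for _ in range(20):
        atlas, chrom_len = random_landscape(rng, n_qtls=int(rng.integers(1, 51)),
                                            chrom_len=int(rng.integers(200, 10_001)))
        per_bp = {}
        for q in atlas.qtls:
            for pos in range(q.start, q.end + 1):
                per_bp.setdefault(pos, set()).add(q.qtl_id)
        segs = decompose(atlas, "A1")
        # disjoint, sorted, every covered bp in exactly one segment
        covered = {}
        for seg in segs:
            for pos in range(seg.start, seg.end + 1):
                assert pos not in covered
                covered[pos] = set(seg.qtl_ids)
        assert covered == per_bp


def test_overlap_region_from_hand_example():
    atlas = make_atlas([make_qtl("q1", "A1", 100, 200, "S"),
                        make_qtl("q2", "A1", 150, 300, "Y")])
    regions, summary = call_overlap_regions(atlas)
    (r,) = regions
    assert (r.start, r.end, r.multiplicity, r.n_qtls) == (150, 200, 2, 2)
    assert r.per_category_counts["S"] == r.per_category_counts["Y"] == 1
    assert summary.total == 1


def test_five_categories_in_one_region():
    atlas = make_atlas([make_qtl(f"q{c}", "A1", 10, 20, c) for c in "ABHSY"])
    regions, _ = call_overlap_regions(atlas)
    (r,) = regions
    assert (r.start, r.end, r.multiplicity, r.n_qtls) == (10, 20, 5, 5)


@pytest.mark.parametrize("policy", ["constant_category_set", "constant_multiplicity"])
def test_overlap_regions_equal_perbp_oracle(policy):
    """The central equivalence: sweep-line + merge == exhaustive per-bp tally."""
    rng = np.random.default_rng(29)
    for _ in range(40):
        atlas, chrom_len = random_landscape(rng)
        regions, _ = call_overlap_regions(atlas, RunConfig(region_merge_policy=policy))
        got = [(r.start, r.end, r.qtl_ids, r.per_category_counts) for r in regions]
        assert got == perbp_regions(atlas.qtls, chrom_len, 2, policy)


def test_region_nesting_across_min_categories():
    rng = np.random.default_rng(31)
    for _ in range(10):
        atlas, _ = random_landscape(rng)
        by_k = {}
        for k in (2, 3, 4):
            by_k[k], _ = call_overlap_regions(atlas, RunConfig(min_categories=k))
        for k in (3, 4):
            for r in by_k[k]:
                assert any(p.start <= r.start and r.end <= p.end for p in by_k[k - 1])


def test_permutation_invariance_of_region_calling():
    rng = np.random.default_rng(37)
    atlas, _ = random_landscape(rng, n_qtls=40)
    shuffled_qtls = list(atlas.qtls)
    rng.shuffle(shuffled_qtls)
    atlas2 = make_atlas(shuffled_qtls, dict(atlas.assembly.chromosomes))
    r1, _ = call_overlap_regions(atlas)
    r2, _ = call_overlap_regions(atlas2)
    assert r1 == r2


def test_segment_lengths_conserve_union_coverage():
    rng = np.random.default_rng(41)
    for _ in range(10):
        atlas, _ = random_landscape(rng)
        seg_total = sum(s.length for s in decompose(atlas, "A1"))
        assert seg_total == covered_length(atlas)


@given(st.lists(st.tuples(st.integers(1, 500), st.integers(0, 80)),
                min_size=1, max_size=30))
def test_segment_conservation_property(intervals):
    qtls = [make_qtl(f"q{i}", "A1", s, s + span, "SYABH"[i % 5])
            for i, (s, span) in enumerate(intervals)]
    atlas = make_atlas(qtls, {"A1": 1000})
    assert sum(s.length for s in decompose(atlas, "A1")) == covered_length(atlas)


def test_category_count_identity():
    """Sum of per-category distinct-QTL counts equals n_qtls exactly (each
    QTL has one category)."""
    rng = np.random.default_rng(43)
    atlas, _ = random_landscape(rng, n_qtls=50)
    regions, summary = call_overlap_regions(atlas)
    assert summary.total == len(regions)
    for r in regions:
        assert sum(r.per_category_counts.values()) == r.n_qtls


# ------------------------------------------------------------- hot regions ----

def test_hot_flag_is_strictly_greater_than_threshold():
    qtls = [make_qtl(f"s{i}", "A1", 10, 90, "S") for i in range(51)]
    qtls += [make_qtl(f"y{i}", "A1", 10, 90, "Y") for i in range(50)]
    atlas = make_atlas(qtls)
    regions, _ = call_overlap_regions(atlas)
    (r,) = detect_hot_regions(regions, 100)
    assert r.n_qtls == 101 and r.hot
    (r,) = detect_hot_regions(regions, 101)
    assert not r.hot  # n_qtls == threshold is not hot


# ------------------------------------------------------------- specificity ----

def _specificity_atlas():
    qtls = [
        make_qtl("q1", "A1", 10, 50, "S", country="China", population="Pop1"),
        make_qtl("q2", "A1", 10, 50, "S", country="China", population="Pop2"),
        make_qtl("q3", "A1", 10, 50, "S", country="China", population="Pop3"),
        make_qtl("q4", "A1", 10, 50, "Y", country="China", population="Pop4"),
        make_qtl("q5", "A1", 100, 150, "S", country="China", population="Pop1"),
        make_qtl("q6", "A1", 100, 150, "Y", country="Canada", population="Pop5"),
    ]
    return make_atlas(qtls)


def test_single_country_region_is_environment_specific():
    atlas = _specificity_atlas()
    regions, _ = call_overlap_regions(atlas)
    regions = specificity_scan(regions, atlas, "country", 2)
    by_start = {r.start: r for r in regions}
    assert by_start[10].environment_specific and by_start[10].specific_value == "China"
    assert not by_start[100].environment_specific  # China + Canada


def test_population_specificity_requires_min_qtls():
    atlas = make_atlas([make_qtl("q1", "A1", 10, 50, "S", population="PopX"),
                        make_qtl("q2", "A1", 10, 50, "Y", population="PopX")])
    regions, _ = call_overlap_regions(atlas)
    (r,) = specificity_scan(regions, atlas, "population", 2)
    assert r.population_specific and r.specific_value == "PopX"
    (r,) = specificity_scan(regions, atlas, "population", 3)
    assert not r.population_specific


def test_specificity_unknown_field_errors():
    atlas = _specificity_atlas()
    regions, _ = call_overlap_regions(atlas)
    with pytest.raises(QtlAtlasError, match="field"):
        specificity_scan(regions, atlas, "ecotype", 2)


# ---------------------------------------------------------- colocalization ----

def test_trait_pair_simple_intersection(catalog):
    atlas = make_atlas([
        make_qtl("oc", "A1", 1, 10, "S", trait="oil content"),
        make_qtl("sy", "A1", 5, 20, "Y", trait="seed yield"),
    ])
    (r,) = trait_pair_colocalization(atlas, "oil content", "seed yield", catalog)
    assert (r.start, r.end) == (5, 10)
    assert r.qtl_ids == {"oc", "sy"}


def test_trait_pair_disjoint_intervals_empty(catalog):
    atlas = make_atlas([
        make_qtl("oc", "A1", 1, 10, "S", trait="oil content"),
        make_qtl("sy", "A1", 50, 60, "Y", trait="seed yield"),
    ])
    assert trait_pair_colocalization(atlas, "oil content", "seed yield", catalog) == []


def test_trait_pair_unknown_trait_errors(catalog):
    atlas = make_atlas([make_qtl("q", "A1", 1, 10)])
    with pytest.raises(QtlAtlasError, match="uncatalogued"):
        trait_pair_colocalization(atlas, "oil content", "unicorn length", catalog)


def test_trait_pair_equals_perbp_oracle(catalog):
    rng = np.random.default_rng(47)
    for _ in range(25):
        atlas, chrom_len = random_landscape(rng)
        got = [(r.start, r.end, r.qtl_ids)
               for r in trait_pair_colocalization(atlas, "oil content", "seed yield", catalog)]
        assert got == perbp_colocalization(atlas.qtls, chrom_len,
                                           "oil content", "seed yield")


# ---------------------------------------------------------------- summaries ----

def test_summarize_counts_by_multiplicity():
    atlas = make_atlas(
        [make_qtl(f"q{c}", "A1", 10, 20, c) for c in "ABHSY"]
        + [make_qtl("x1", "A1", 100, 120, "S"), make_qtl("x2", "A1", 100, 120, "Y")]
        + [make_qtl("x3", "C1", 10, 30, "S"), make_qtl("x4", "C1", 10, 30, "Y")]
    )
    regions, summary = call_overlap_regions(atlas)
    assert summary.by_multiplicity == {5: 1, 2: 2}
    assert summary.total == 3 == sum(summary.by_multiplicity.values())
    assert summary.per_chromosome["A1"] == 2 and summary.per_chromosome["C1"] == 1


def test_summarize_empty_region_list():
    atlas = make_atlas([make_qtl("q1", "A1", 10, 20, "S")])
    regions, summary = call_overlap_regions(atlas)
    assert regions == [] and summary.total == 0 and summary.by_multiplicity == {}
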