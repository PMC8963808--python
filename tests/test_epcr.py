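"""e-PCR and sequence anchoring against constructed cases and the exhaustive
sliding-window oracle."""
import numpy as np
import pytest

from qtlatlas import EpcrParams, MarkerSpec, QtlAtlasError, anchor_markers
from qtlatlas.epcr import epcr_search, hamming_occurrences, revcomp, sequence_anchor

from conftest import make_assembly, random_genome
from oracles import brute_epcr, brute_hamming

FWD = "ACGTACCGTA"  # 10 nt
REV = "TTACGCAAGG"


def _genome_with_amplicon(prefix="AA", gap="TTTT", suffix="AA"):
    seq = prefix + FWD + gap + revcomp(REV) + suffix
    return make_assembly({"A1": len(seq)}, {"A1": seq})


def test_exact_amplicon_found_with_expected_coordinates():
    genome = _genome_with_amplicon()
    (hit,) = epcr_search(genome, FWD, REV, EpcrParams(0, (10, 30)))
    assert (hit.chrom_id, hit.start, hit.strand) == ("A1", 3, "+")
    assert hit.end == 2 + len(FWD) + 4 + len(REV)
    assert hit.product_size == hit.end - hit.start + 1 == 24
    assert hit.mismatches_fwd == hit.mismatches_rev == 0


def test_size_window_filters_out_the_amplicon():
    genome = _genome_with_amplicon()
    assert epcr_search(genome, FWD, REV, EpcrParams(0, (2, 10))) == []
    assert epcr_search(genome, FWD, REV, EpcrParams(0, (25, 5000))) == []


def test_primer_validation():
    genome = _genome_with_amplicon()
    with pytest.raises(QtlAtlasError, match="shorter"):
        epcr_search(genome, "ACGTAC", REV)
    with pytest.raises(QtlAtlasError, match="non-IUPAC"):
        epcr_search(genome, "ACGTACGTAX", REV)


def test_iupac_primer_matches_expansion_but_genome_n_matches_nothing():
    seq = "AA" + "ACGTACCGTA" + "TT"
    genome = make_assembly({"A1": len(seq)}, {"A1": seq})
    # R expands to A/G at the first position
    assert hamming_occurrences(genome.sequence("A1"), "RCGTACCGTA", 0) == [(2, 0)]
    n_seq = seq.replace("ACGTACCGTA", "NCGTACCGTA")
    assert hamming_occurrences(n_seq, "ACGTACCGTA", 0) == []
    assert hamming_occurrences(n_seq, "NCGTACCGTA", 1) == [(2, 1)]  # N in genome: mismatch


@pytest.mark.parametrize("max_mm", [0, 1, 2])
def test_hamming_search_equals_naive_scan(max_mm):
    rng = np.random.default_rng(101 + max_mm)
    for _ in range(30):
        n = int(rng.integers(50, 2000))
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
        m = int(rng.integers(max_mm + 2, 22))
        pat = "".join("ACGT"[i] for i in rng.integers(0, 4, size=m))
        assert hamming_occurrences(seq, pat, max_mm) == brute_hamming(seq, pat, max_mm)


def test_epcr_equals_bruteforce_on_random_instances():
    rng = np.random.default_rng(7)
    for trial in range(30):
        genome = random_genome(rng, {"A1": int(rng.integers(200, 3000)),
                                     "C1": int(rng.integers(200, 3000))})
        max_mm = trial % 3
        # embed a mutated amplicon on a random chromosome so hits exist
        chrom = ("A1", "C1")[trial % 2]
        seq = list(genome.sequences[chrom])
        fwd = "".join("ACGT"[i] for i in rng.integers(0, 4, size=18))
        rev = "".join("ACGT"[i] for i in rng.integers(0, 4, size=18))
        pos = int(rng.integers(0, len(seq) - 120))
        ins = fwd + "".join(seq[pos + 18 : pos + 82]) + revcomp(rev)
        seq[pos : pos + 100] = ins
        if max_mm:
            seq[pos] = "ACGT"[(("ACGT".index(seq[pos])) + 1) % 4]
        genome.sequences[chrom] = "".join(seq)
        params = EpcrParams(max_mm, (60, 300))
        assert epcr_search(genome, fwd, rev, params) == [
            tuple(h) for h in brute_epcr(genome, fwd, rev, params)
        ]


def test_hit_set_grows_monotonically_with_mismatch_and_size():
    rng = np.random.default_rng(11)
    genome = random_genome(rng, {"A1": 4000})
    fwd = genome.sequences["A1"][100:118]
    rev = revcomp(genome.sequences["A1"][300:318])
    spans = lambda hits: {(h.chrom_id, h.start, h.end, h.strand) for h in hits}
    prev = set()
    for mm in (0, 1, 2):
        cur = spans(epcr_search(genome, fwd, rev, EpcrParams(mm, (50, 500))))
        assert prev <= cur
        prev = cur
    narrow = spans(epcr_search(genome, fwd, rev, EpcrParams(1, (100, 300))))
    wide = spans(epcr_search(genome, fwd, rev, EpcrParams(1, (50, 1000))))
    assert narrow <= wide


def test_strand_symmetry_under_genome_reverse_complement():
    rng = np.random.default_rng(13)
    genome = random_genome(rng, {"A1": 3000})
    fwd = genome.sequences["A1"][500:518]
    rev = revcomp(genome.sequences["A1"][700:718])
    params = EpcrParams(1, (50, 600))
    hits = epcr_search(genome, fwd, rev, params)
    assert hits, "construction should yield at least one hit"
    L = 3000
    flipped = make_assembly({"A1": L}, {"A1": revcomp(genome.sequences["A1"])})
    mirrored = {
        (h.chrom_id, L - h.end + 1, L - h.start + 1,
         "-" if h.strand == "+" else "+", h.mismatches_fwd, h.mismatches_rev)
        for h in hits
    }
    got = {
        (h.chrom_id, h.start, h.end, h.strand, h.mismatches_fwd, h.mismatches_rev)
        for h in epcr_search(flipped, fwd, rev, params)
    }
    assert got == mirrored


# -------------------------------------------------------- sequence anchor ----

def test_sequence_anchor_finds_minus_strand_match():
    rng = np.random.default_rng(17)
    genome = random_genome(rng, {"A1": 1000})
    marker = revcomp(genome.sequences["A1"][400:420])
    hits = [h for h in sequence_anchor(genome, marker, 0) if h.strand == "-"]
    assert any(h.start == 401 and h.end == 420 for h in hits)


def test_sequence_anchor_mismatch_monotonicity_and_oracle():
    rng = np.random.default_rng(19)
    genome = random_genome(rng, {"A1": 2000})
    marker = genome.sequences["A1"][100:120]
    h0 = {tuple(h) for h in sequence_anchor(genome, marker, 0)}
    h1 = {tuple(h) for h in sequence_anchor(genome, marker, 1)}
    assert {t[:4] for t in h0} <= {t[:4] for t in h1}
    seq = genome.sequences["A1"]
    expect = {("A1", s + 1, s + 20, "+", mm) for s, mm in brute_hamming(seq, marker, 1)}
    expect |= {("A1", s + 1, s + 20, "-", mm) for s, mm in brute_hamming(seq, revcomp(marker), 1)}
    assert h1 == expect


def test_sequence_anchor_rejects_short_sequence():
    genome = _genome_with_amplicon()
    with pytest.raises(QtlAtlasError, match="shorter"):
        sequence_anchor(genome, "ACGTACGTACGTAC", 0)  # 14 nt


# -------------------------------------------------------------- anchoring ----

def test_anchor_unique_hit_maps_to_amplicon_midpoint():
    genome = _genome_with_amplicon()
    spec = MarkerSpec("m1", "primer_pair", forward_primer=FWD, reverse_primer=REV)
    marker_map, report = anchor_markers(genome, [spec], EpcrParams(0, (10, 30)))
    assert marker_map == {"m1": ("A1", (3 + 26) // 2)}
    assert report.n_anchored == 1 and not report.unanchored


def test_best_mismatch_policy_resolves_two_loci():
    marker = "ACGTTGCACGGTTACAACGT"
    mutated = "T" + marker[1:]
    seq = "CC" + marker + "CCCCCC" + mutated + "CC"
    genome = make_assembly({"A1": len(seq)}, {"A1": seq})
    spec = MarkerSpec("m1", "sequence", sequence=marker)
    marker_map, _ = anchor_markers(genome, [spec], EpcrParams(1, (10, 5000)),
                                   "best_mismatch_then_fail")
    assert marker_map["m1"] == ("A1", (3 + 22) // 2)
    _, report = anchor_markers(genome, [spec], EpcrParams(1, (10, 5000)), "fail")
    assert report.unanchored == [("m1", "ambiguous")]


def test_position_markers_pass_through_and_failures_are_reported_not_raised():
    genome = _genome_with_amplicon()
    specs = [
        MarkerSpec("mpos", "position", position=("A1", 7)),
        MarkerSpec("mmiss", "primer_pair",
                   forward_primer="GGGGGGGGGG", reverse_primer="CCCCCCCCCC"),
    ]
    marker_map, report = anchor_markers(genome, specs, EpcrParams(0, (10, 30)))
    assert marker_map == {"mpos": ("A1", 7)}
    assert report.unanchored == [("mmiss", "no_hit")]


def test_planted_synthetic_markers_all_anchor_at_true_coordinates(bundle_dir, bundle_manifest):
    from qtlatlas.io import load_genome_fasta, read_marker_table

    genome = load_genome_fasta(bundle_dir / "genome.fa")
    specs = read_marker_table(bundle_dir / "markers.tsv")
    marker_map, report = anchor_markers(genome, specs)
    truth = bundle_manifest["markers"]
    assert report.n_anchored == report.n_markers == len(truth)
    for mid, t in truth.items():
        assert marker_map[mid] == (t["chrom"], t["pos"])
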