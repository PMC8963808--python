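"""Independent brute-force oracles used by the test suite.

These deliberately use the naive O(n*m) / per-base-pair formulations so they
share no code path with the package's seeded search and sweep-line
implementations.
"""
from __future__ import annotations

import numpy as np

from qtlatlas.epcr import IUPAC_EXPANSION, revcomp
from qtlatlas.model import CATEGORY_CODES

# ----------------------------------------------------------------- e-PCR ----

def brute_hamming(seq: str, pattern: str, max_mm: int) -> list[tuple[int, int]]:
    """Every start position checked character by character."""
    m = len(pattern)
    out = []
    for s in range(len(seq) - m + 1):
        mm = 0
        for j in range(m):
            if seq[s + j] not in IUPAC_EXPANSION[pattern[j]]:
                mm += 1
                if mm > max_mm:
                    break
        if mm <= max_mm:
            out.append((s, mm))
    return out


def brute_epcr(genome, fwd: str, rev: str, params) -> list[tuple]:
    """Exhaustive sliding-window e-PCR over every start position and
    orientation; returns the same hit tuples as epcr_search."""
    fwd, rev = fwd.upper(), rev.upper()
    lo, hi = params.size_range
    hits = []

    def pair(seq, chrom, left, right_rc, strand, swap):
        lh = brute_hamming(seq, left, params.max_mismatch)
        rh = brute_hamming(seq, right_rc, params.max_mismatch)
        for ls, lmm in lh:
            for rs, rmm in rh:
                if rs < ls:
                    continue
                size = rs + len(right_rc) - ls
                if lo <= size <= hi:
                    mf, mr = (rmm, lmm) if swap else (lmm, rmm)
                    hits.append((chrom, ls + 1, rs + len(right_rc), strand, mf, mr, size))

    for chrom, _length in genome.chromosomes:
        seq = genome.sequences[chrom]
        pair(seq, chrom, fwd, revcomp(rev), "+", False)
        if params.search_both_orientations:
            pair(seq, chrom, rev, revcomp(fwd), "-", True)
    order = genome.chrom_order()
    hits.sort(key=lambda h: (order[h[0]], h[1], h[2], h[3]))
    seen, unique = set(), []
    for h in hits:
        key = h[:4]
        if key not in seen:
            seen.add(key)
            unique.append(h)
    return unique


# ------------------------------------------------------- overlap regions ----

CAT_BIT = {c: 1 << i for i, c in enumerate(CATEGORY_CODES)}
_POPCNT = np.array([bin(v).count("1") for v in range(32)], dtype=np.uint8)


def perbp_regions(qtls, chrom_len: int, min_categories: int, policy: str):
    """Per-base-pair tally of present categories; maximal qualifying runs
    split where the category set (or, under constant_multiplicity, the
    count) changes. Returns (start, end, qtl_ids, per_category_counts)."""
    mask = np.zeros(chrom_len + 1, dtype=np.uint8)  # 1-based
    for q in qtls:
        mask[q.start : q.end + 1] |= CAT_BIT[q.category]
    pop = _POPCNT[mask]
    runs = []
    run_start = None
    run_key = None
    for pos in range(1, chrom_len + 1):
        qual = pop[pos] >= min_categories
        key = int(mask[pos]) if policy == "constant_category_set" else int(pop[pos])
        if qual and run_start is not None and key == run_key:
            continue
        if run_start is not None:
            runs.append((run_start, pos - 1))
        run_start, run_key = (pos, key) if qual else (None, None)
    if run_start is not None:
        runs.append((run_start, chrom_len))
    out = []
    for a, b in runs:
        ids = frozenset(q.qtl_id for q in qtls if not (q.end < a or q.start > b))
        counts = {c: 0 for c in CATEGORY_CODES}
        for q in qtls:
            if not (q.end < a or q.start > b):
                counts[q.category] += 1
        out.append((a, b, ids, counts))
    return out


def perbp_colocalization(qtls, chrom_len: int, trait_a: str, trait_b: str):
    """Maximal runs of bp covered by >= 1 QTL of each trait; returns
    (start, end, qtl_ids-of-the-two-traits)."""
    norm = lambda t: t.strip().lower()
    cov_a = np.zeros(chrom_len + 1, dtype=bool)
    cov_b = np.zeros(chrom_len + 1, dtype=bool)
    for q in qtls:
        if norm(q.trait_name) == norm(trait_a):
            cov_a[q.start : q.end + 1] = True
        elif norm(q.trait_name) == norm(trait_b):
            cov_b[q.start : q.end + 1] = True
    both = cov_a & cov_b
    out = []
    run_start = None
    for pos in range(1, chrom_len + 1):
        if both[pos]:
            if run_start is None:
                run_start = pos
        elif run_start is not None:
            out.append((run_start, pos - 1))
            run_start = None
    if run_start is not None:
        out.append((run_start, chrom_len))
    result = []
    for a, b in out:
        ids = frozenset(
            q.qtl_id for q in qtls
            if norm(q.trait_name) in (norm(trait_a), norm(trait_b))
            and not (q.end < a or q.start > b)
        )
        result.append((a, b, ids))
    return result
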