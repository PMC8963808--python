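"""In-silico PCR (e-PCR) and direct sequence anchoring of STS markers.

Matching is Hamming (no indels), the classical STS-search model. Primer
letters may be IUPAC ambiguity codes and match their expansion set; genome
letters must be concrete A/C/G/T to match (an N in the genome matches
nothing). Pure-ACGT primers are searched with a pigeonhole seed-and-verify
scheme (split into max_mismatch+1 exact pieces, verify candidates); ambiguous
primers fall back to a full scan.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

import numpy as np

from .model import (
    GenomeAssembly,
    MarkerSpec,
    MIN_MARKER_SEQUENCE_LENGTH,
    MIN_PRIMER_LENGTH,
    QtlAtlasError,
)

IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


class AmpliconHit(NamedTuple):
    """One predicted PCR product. ``strand`` is the strand the *forward*
    primer binds; coordinates span both primer footprints, 1-based inclusive."""

    chrom_id: str
    start: int
    end: int
    strand: str
    mismatches_fwd: int
    mismatches_rev: int
    product_size: int


class SequenceHit(NamedTuple):
    chrom_id: str
    start: int
    end: int
    strand: str
    mismatches: int


@dataclass
class EpcrParams:
    max_mismatch: int = 1
    size_range: tuple[int, int] = (50, 5000)
    search_both_orientations: bool = True

    def __post_init__(self) -> None:
        if self.max_mismatch < 0:
            raise QtlAtlasError("max_mismatch must be >= 0")
        if self.size_range[0] > self.size_range[1]:
            raise QtlAtlasError("size_range min > max")


def _validate_primer(primer: str, what: str) -> str:
    primer = primer.upper()
    if len(primer) < MIN_PRIMER_LENGTH:
        raise QtlAtlasError(f"{what} shorter than {MIN_PRIMER_LENGTH} nt")
    bad = set(primer) - set(IUPAC_EXPANSION)
    if bad:
        raise QtlAtlasError(f"{what} contains non-IUPAC letters: {sorted(bad)}")
    return primer


def _count_mismatches(seq: str, pos: int, pattern: str, limit: int) -> int:
    """Mismatches of pattern against seq[pos:pos+len(pattern)], early exit
    past limit (returns limit+1)."""
    mm = 0
    for j, pc in enumerate(pattern):
        if seq[pos + j] not in IUPAC_EXPANSION[pc]:
            mm += 1
            if mm > limit:
                return mm
    return mm


def _scan_full(seq: str, pattern: str, max_mm: int) -> list[tuple[int, int]]:
    """Vectorized full scan; used for ambiguous patterns. Returns
    (0-based start, mismatches)."""
    n, m = len(seq), len(pattern)
    if m > n:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    width = n - m + 1
    mism = np.zeros(width, dtype=np.int32)
    for j, pc in enumerate(pattern):
        allowed = np.array([ord(c) for c in IUPAC_EXPANSION[pc]], dtype=np.uint8)
        ok = np.isin(arr[j : j + width], allowed)
        mism += ~ok
    starts = np.flatnonzero(mism <= max_mm)
    return [(int(s), int(mism[s])) for s in starts]


def hamming_occurrences(seq: str, pattern: str, max_mm: int) -> list[tuple[int, int]]:
    """All 0-based start positions where ``pattern`` matches ``seq`` within
    ``max_mm`` Hamming mismatches, with the mismatch count."""
    pattern = pattern.upper()
    m = len(pattern)
    if m == 0 or m > len(seq):
        return []
    if set(pattern) - set("ACGT") or m < max_mm + 1:
        return _scan_full(seq, pattern, max_mm)
    if max_mm == 0:
        out = []
        i = seq.find(pattern)
        while i != -1:
            out.append((i, 0))
            i = seq.find(pattern, i + 1)
        return out
    # pigeonhole: any match with <= max_mm mismatches contains one exact piece
    k = max_mm + 1
    bounds = [round(i * m / k) for i in range(k + 1)]
    candidates: set[int] = set()
    n = len(seq)
    for i in range(k):
        piece = pattern[bounds[i] : bounds[i + 1]]
        off = bounds[i]
        j = seq.find(piece)
        while j != -1:
            s = j - off
            if 0 <= s <= n - m:
                candidates.add(s)
            j = seq.find(piece, j + 1)
    out = []
    for s in sorted(candidates):
        mm = _count_mismatches(seq, s, pattern, max_mm)
        if mm <= max_mm:
            out.append((s, mm))
    return out


def _pair_hits(
    chrom: str,
    seq: str,
    left: str,
    right_rc: str,
    max_mm: int,
    size_range: tuple[int, int],
    strand: str,
    swap_mm: bool,
) -> list[AmpliconHit]:
    """Pair left-primer plus-strand sites with downstream reverse-complement
    sites of the right primer; keep products inside the size window."""
    lo, hi = size_range
    lhits = hamming_occurrences(seq, left, max_mm)
    if not lhits:
        return []
    rhits = hamming_occurrences(seq, right_rc, max_mm)
    out = []
    rlen = len(right_rc)
    for ls, lmm in lhits:
        for rs, rmm in rhits:
            if rs < ls:
                continue
            size = rs + rlen - ls
            if lo <= size <= hi:
                mf, mr = (rmm, lmm) if swap_mm else (lmm, rmm)
                out.append(AmpliconHit(chrom, ls + 1, rs + rlen, strand, mf, mr, size))
    return out


def epcr_search(
    genome: GenomeAssembly,
    forward_primer: str,
    reverse_primer: str,
    params: Optional[EpcrParams] = None,
) -> list[AmpliconHit]:
    """Find all putative amplicons of a primer pair on the assembly.

    A plus-strand hit has the forward primer matching the plus strand and the
    reverse complement of the reverse primer matching downstream, with the
    product size inside ``params.size_range``. With
    ``search_both_orientations`` the primer roles are also swapped (forward
    primer on the minus strand, strand "-").
    """
    params = params or EpcrParams()
    fwd = _validate_primer(forward_primer, "forward primer")
    rev = _validate_primer(reverse_primer, "reverse primer")
    hits: list[AmpliconHit] = []
    for chrom, _length in genome.chromosomes:
        if genome.sequences is None or chrom not in genome.sequences:
            raise QtlAtlasError(f"no sequence loaded for chromosome {chrom!r}")
        seq = genome.sequences[chrom]
        hits.extend(
            _pair_hits(chrom, seq, fwd, revcomp(rev), params.max_mismatch,
                       params.size_range, "+", swap_mm=False)
        )
        if params.search_both_orientations:
            hits.extend(
                _pair_hits(chrom, seq, rev, revcomp(fwd), params.max_mismatch,
                           params.size_range, "-", swap_mm=True)
            )
    order = genome.chrom_order()
    hits.sort(key=lambda h: (order[h.chrom_id], h.start, h.end, h.strand))
    # palindromic primer pairs can yield the same span in both roles
    seen: set[tuple] = set()
    unique = []
    for h in hits:
        key = (h.chrom_id, h.start, h.end, h.strand)
        if key not in seen:
            seen.add(key)
            unique.append(h)
    return unique


def sequence_anchor(
    genome: GenomeAssembly, marker_sequence: str, max_mismatch: int = 1
) -> list[SequenceHit]:
    """All plus- and minus-strand matches of a marker sequence within
    ``max_mismatch`` Hamming distance."""
    seq = marker_sequence.upper()
    if len(seq) < MIN_MARKER_SEQUENCE_LENGTH:
        raise QtlAtlasError(
            f"marker sequence shorter than {MIN_MARKER_SEQUENCE_LENGTH} nt"
        )
    bad = set(seq) - set(IUPAC_EXPANSION)
    if bad:
        raise QtlAtlasError(f"marker sequence contains non-IUPAC letters: {sorted(bad)}")
    hits: list[SequenceHit] = []
    m = len(seq)
    for chrom, _length in genome.chromosomes:
        text = genome.sequence(chrom)
        for s, mm in hamming_occurrences(text, seq, max_mismatch):
            hits.append(SequenceHit(chrom, s + 1, s + m, "+", mm))
        for s, mm in hamming_occurrences(text, revcomp(seq), max_mismatch):
            hits.append(SequenceHit(chrom, s + 1, s + m, "-", mm))
    order = genome.chrom_order()
    hits.sort(key=lambda h: (order[h.chrom_id], h.start, h.end, h.strand))
    return hits


@dataclass
class AnchoringReport:
    n_markers: int = 0
    n_anchored: int = 0
    unanchored: list[tuple[str, str]] = field(default_factory=list)  # (marker_id, reason)

    @property
    def n_unanchored(self) -> int:
        return len(self.unanchored)


def _midpoint(start: int, end: int) -> int:
    # floor midpoint; exact for odd-length spans (the simulator plants odd ones)
    return (start + end) // 2


def anchor_markers(
    genome: GenomeAssembly,
    marker_specs: Iterable[MarkerSpec],
    params: Optional[EpcrParams] = None,
    ambiguity_policy: str = "best_mismatch_then_fail",
) -> tuple[dict[str, tuple[str, int]], AnchoringReport]:
    """Resolve each marker to a unique physical position (amplicon/span
    midpoint). Multi-hit markers are resolved per ``ambiguity_policy``:
    ``best_mismatch_then_fail`` keeps a unique minimal-mismatch hit if one
    exists, ``fail`` marks any multi-hit marker unanchored. Failures are
    reported, never raised.
    """
    if ambiguity_policy not in ("best_mismatch_then_fail", "fail"):
        raise QtlAtlasError(f"unknown ambiguity policy: {ambiguity_policy!r}")
    params = params or EpcrParams()
    marker_map: dict[str, tuple[str, int]] = {}
    report = AnchoringReport()
    seen_ids: set[str] = set()
    for spec in marker_specs:
        if spec.marker_id in seen_ids:
            continue
        seen_ids.add(spec.marker_id)
        report.n_markers += 1
        if spec.kind == "position":
            chrom, pos = spec.position
            if chrom not in genome.lengths:
                report.unanchored.append((spec.marker_id, "unknown_chromosome"))
                continue
            marker_map[spec.marker_id] = (chrom, int(pos))
            report.n_anchored += 1
            continue
        if spec.kind == "primer_pair":
            hits = epcr_search(genome, spec.forward_primer, spec.reverse_primer, params)
            scored = [(h.mismatches_fwd + h.mismatches_rev, h.chrom_id, h.start, h.end) for h in hits]
        else:  # sequence
            shits = sequence_anchor(genome, spec.sequence, params.max_mismatch)
            scored = [(h.mismatches, h.chrom_id, h.start, h.end) for h in shits]
        if not scored:
            report.unanchored.append((spec.marker_id, "no_hit"))
            continue
        if len(scored) > 1:
            if ambiguity_policy == "fail":
                report.unanchored.append((spec.marker_id, "ambiguous"))
                continue
            best = min(s[0] for s in scored)
            scored = [s for s in scored if s[0] == best]
            if len(scored) > 1:
                report.unanchored.append((spec.marker_id, "ambiguous"))
                continue
        _, chrom, start, end = scored[0]
        marker_map[spec.marker_id] = (chrom, _midpoint(start, end))
        report.n_anchored += 1
    return marker_map, report
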