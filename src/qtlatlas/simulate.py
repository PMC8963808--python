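"""Ground-truthed synthetic inputs for the whole pipeline.

The generator emulates the combinatorial structure of a multi-study QTL
inventory: several studies/populations/countries, five trait categories with
heavily skewed sizes, QTL intervals of widely varying length including
single-marker point loci, planted co-location regions where 2-5 categories
overlap (realized by construction: their QTLs' intervals equal the region),
one planted hot pile-up, genes inside and outside those regions, and an
Erdos-Renyi interaction graph with planted high-degree hubs.

Marker primers are embedded verbatim into the random genome (exact-match
ground truth, uniqueness verified by exhaustive scan); QTLs planted in one
region share its flanking marker pair, as co-localized QTLs from different
studies share markers in real inventories. Everything is keyed to one RNG
seed; identical configs give byte-identical bundles.
"""
from __future__ import annotations

import json
import math
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .epcr import revcomp
from .io import (
    QTL_TABLE_COLUMNS,
    load_go_slim_vocabulary,
    write_genes_gff3,
    write_genome_fasta,
)
from .model import CATEGORY_CODES, GeneRecord, GenomeAssembly, QtlAtlasError

#: trait-name pools per category used for the synthetic catalog
TRAIT_POOLS: dict[str, tuple[str, ...]] = {
    "A": ("drought tolerance", "heat tolerance", "salt tolerance", "cold tolerance"),
    "B": ("sclerotinia resistance", "blackleg resistance", "clubroot resistance"),
    "H": ("abscisic acid content", "auxin content"),
    "S": ("oil content", "protein content", "glucosinolate content",
          "erucic acid content", "linolenic acid content"),
    "Y": ("seed yield", "plant height", "branch number", "silique number",
          "seed weight", "flowering time"),
}

_AMPLICON_LEN = 101  # odd, so the amplicon midpoint is exact
_PRIMER_LEN = 20
_HALF_AMP = (_AMPLICON_LEN - 1) // 2


@dataclass(frozen=True)
class PlantedRegion:
    chrom_id: str
    start: int
    end: int
    categories: tuple[str, ...]
    n_per_category: int
    hot: bool = False

    @property
    def n_qtls(self) -> int:
        return len(self.categories) * self.n_per_category

    @property
    def multiplicity(self) -> int:
        return len(self.categories)


@dataclass
class SimConfig:
    """Study conditions of the synthetic landscape.

    Category weights mirror the skew of a real inventory
    (349/334/42/1392/2438 over A/B/H/S/Y). ``n_qtls`` counts *background*
    QTLs; planted-region QTLs come on top. ``cm_to_bp`` is 20 kb/cM so the
    1-cM single-marker window (20 kb) fits the 1-Mb toy chromosomes.
    """

    n_chromosomes: int = 4
    chrom_length: int = 1_000_000
    n_studies: int = 6
    countries: tuple[str, ...] = ("China", "Canada", "Germany")
    category_weights: dict[str, float] = field(default_factory=lambda: {
        "A": 0.08, "B": 0.07, "H": 0.01, "S": 0.30, "Y": 0.54,
    })
    n_qtls: int = 300
    fraction_single_marker: float = 0.2
    planted_regions: Optional[tuple[PlantedRegion, ...]] = None  # None -> defaults
    n_planted_hot: int = 1
    hot_qtls_per_category: int = 60  # x2 categories -> 120 QTLs > hot threshold
    n_genes: int = 200
    fraction_genes_in_regions: float = 0.3
    graph_edge_prob: float = 0.05
    n_planted_hubs: int = 3
    hub_degree_target: int = 65  # >= hub threshold (60) + 5
    go_mapped_fraction: float = 0.5
    cm_to_bp: float = 20_000.0
    window_cM: float = 1.0
    exclusion_margin: int = 25_000
    bg_length_min: int = 10_000
    rng_seed: int = 42

    def __post_init__(self) -> None:
        total = sum(self.category_weights.get(c, 0.0) for c in CATEGORY_CODES)
        if abs(total - 1.0) > 1e-6:
            raise QtlAtlasError("category_weights must sum to 1")
        if self.n_chromosomes < 2:
            raise QtlAtlasError("need at least 2 chromosomes")

    @property
    def chrom_names(self) -> list[str]:
        n_a = (self.n_chromosomes + 1) // 2
        return [f"A{i + 1}" for i in range(n_a)] + [
            f"C{i + 1}" for i in range(self.n_chromosomes - n_a)
        ]

    @property
    def bg_length_max(self) -> int:
        # the skewed sub-Mb..multi-Mb length law, capped to fit the toy genome
        return min(5_000_000, self.chrom_length // 5)

    def resolved_planted_regions(self) -> list[PlantedRegion]:
        if self.planted_regions is not None:
            planted = list(self.planted_regions)
        else:
            chroms = self.chrom_names
            L = self.chrom_length

            def at(i: int, lo: float, hi: float, cats, n, hot=False) -> PlantedRegion:
                return PlantedRegion(chroms[i % len(chroms)], int(lo * L), int(hi * L),
                                     tuple(cats), n, hot)

            planted = [
                at(0, 0.20, 0.26, "SY", 2),
                at(1, 0.30, 0.38, "ASY", 2),
                at(2, 0.15, 0.24, "ABSY", 2),
                at(3, 0.40, 0.50, "ABHSY", 2),
            ]
            for h in range(self.n_planted_hot):
                planted.append(at(h, 0.60, 0.70, "SY", self.hot_qtls_per_category, hot=True))
        self._validate_planted(planted)
        return planted

    def _validate_planted(self, planted: list[PlantedRegion]) -> None:
        by_chrom: dict[str, list[PlantedRegion]] = {}
        for r in planted:
            if r.chrom_id not in self.chrom_names:
                raise QtlAtlasError(f"planted region on unknown chromosome {r.chrom_id!r}")
            if not (1 <= r.start < r.end <= self.chrom_length):
                raise QtlAtlasError("planted region out of chromosome bounds")
            for c in r.categories:
                if c not in CATEGORY_CODES:
                    raise QtlAtlasError(f"planted region: bad category {c!r}")
            by_chrom.setdefault(r.chrom_id, []).append(r)
        for regs in by_chrom.values():
            regs = sorted(regs, key=lambda r: r.start)
            for a, b in zip(regs, regs[1:]):
                if b.start - self.exclusion_margin <= a.end + self.exclusion_margin:
                    raise QtlAtlasError("planted regions overlap (including margins)")


@dataclass
class SyntheticBundle:
    config: SimConfig
    genome: GenomeAssembly
    marker_truth: dict[str, dict]  # marker_id -> {chrom, pos, fwd, rev}
    qtl_rows: list[dict]
    genes: list[GeneRecord]
    edges: list[tuple[str, str]]
    go_mapping: dict[str, str]
    manifest: dict


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _rand_primer(rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=_PRIMER_LEN))


def _pack_kmer(kmer: str) -> int:
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    h = 0
    for j, ch in enumerate(kmer):
        h |= code[ch] << (2 * j)
    return h


def _kmer_counts(chrom_arrays, kmers: set[str]) -> dict[str, int]:
    """Exhaustive genome-wide occurrence counts of 20-mers, via an exact
    2-bit-packed rolling window (injective encoding, pure-ACGT genome)."""
    w = _PRIMER_LEN
    lut = np.zeros(256, dtype=np.uint64)
    for i, ch in enumerate("ACGT"):
        lut[ord(ch)] = i
    hashes = []
    for arr in chrom_arrays:
        if len(arr) < w:
            continue
        codes = lut[arr]
        h = np.zeros(len(arr) - w + 1, dtype=np.uint64)
        for j in range(w):
            h |= codes[j : len(arr) - w + 1 + j] << np.uint64(2 * j)
        hashes.append(h)
    all_h = np.sort(np.concatenate(hashes)) if hashes else np.array([], dtype=np.uint64)
    out = {}
    for kmer in kmers:
        v = np.uint64(_pack_kmer(kmer))
        out[kmer] = int(np.searchsorted(all_h, v, "right") - np.searchsorted(all_h, v, "left"))
    return out


class _Placer:
    """Tracks occupied amplicon spans and planted exclusion zones per
    chromosome (0/1-based: spans are 1-based inclusive)."""

    def __init__(self, zones: dict[str, list[tuple[int, int]]]):
        self.zones = zones
        self.occupied: dict[str, list[tuple[int, int]]] = {}

    @staticmethod
    def _hits(spans, s, e) -> bool:
        return any(not (e < a or s > b) for a, b in spans)

    def in_zone(self, chrom, s, e) -> bool:
        return self._hits(self.zones.get(chrom, ()), s, e)

    def amplicon_free(self, chrom, pos) -> bool:
        return not self._hits(self.occupied.get(chrom, ()), pos - _HALF_AMP, pos + _HALF_AMP)

    def reserve(self, chrom, pos) -> None:
        self.occupied.setdefault(chrom, []).append((pos - _HALF_AMP, pos + _HALF_AMP))


def simulate_landscape(config: Optional[SimConfig] = None, outdir=None) -> SyntheticBundle:
    """Generate the full synthetic bundle; if ``outdir`` is given, write
    genome.fa, chrom_sizes.tsv, markers.tsv, qtls.tsv, genes.gff3, edges.tsv,
    go_slim.tsv, trait_catalog.tsv and manifest.json there."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.rng_seed)
    chroms = config.chrom_names
    L = config.chrom_length
    base = np.frombuffer(b"ACGT", dtype=np.uint8)
    arrays = {c: base[rng.integers(0, 4, size=L)].copy() for c in chroms}

    planted = config.resolved_planted_regions()
    zones = {}
    for r in planted:
        zones.setdefault(r.chrom_id, []).append(
            (r.start - config.exclusion_margin, r.end + config.exclusion_margin)
        )
    placer = _Placer(zones)

    cats = list(CATEGORY_CODES)
    weights = np.array([config.category_weights[c] for c in cats])
    half_window = _round_half_up(config.window_cM * config.cm_to_bp / 2)

    # ---- QTL truth -------------------------------------------------------
    marker_truth: dict[str, dict] = {}
    qtl_truth: list[dict] = []

    def new_marker(mid: str, chrom: str, pos: int) -> None:
        if not placer.amplicon_free(chrom, pos):
            raise QtlAtlasError(f"marker {mid}: amplicon collision at {chrom}:{pos}")
        placer.reserve(chrom, pos)
        marker_truth[mid] = {"chrom": chrom, "pos": int(pos),
                             "fwd": _rand_primer(rng), "rev": _rand_primer(rng)}

    for ri, region in enumerate(planted):
        left_id, right_id = f"M_R{ri}_L", f"M_R{ri}_R"
        new_marker(left_id, region.chrom_id, region.start)
        new_marker(right_id, region.chrom_id, region.end)
        for cat in region.categories:
            for k in range(region.n_per_category):
                qtl_truth.append({
                    "chrom": region.chrom_id, "start": region.start, "end": region.end,
                    "category": cat,
                    "trait": TRAIT_POOLS[cat][int(rng.integers(len(TRAIT_POOLS[cat])))],
                    "left": left_id, "right": right_id,
                    "expected_provenance": "two_markers", "planted_region": ri,
                })

    n_bg = config.n_qtls
    log_lo, log_hi = math.log(config.bg_length_min), math.log(config.bg_length_max)
    pad = _HALF_AMP + 10
    for j in range(n_bg):
        cat = cats[int(rng.choice(len(cats), p=weights))]
        trait = TRAIT_POOLS[cat][int(rng.integers(len(TRAIT_POOLS[cat])))]
        single = bool(rng.random() < config.fraction_single_marker)
        placed = False
        for _attempt in range(500):
            chrom = chroms[int(rng.integers(len(chroms)))]
            if single:
                lo, hi = half_window + pad, L - half_window - pad
                if lo >= hi:
                    continue
                pos = int(rng.integers(lo, hi + 1))
                s, e = pos - half_window, pos + half_window
                if placer.in_zone(chrom, s - pad, e + pad) or not placer.amplicon_free(chrom, pos):
                    continue
                mid = f"M_Q{j:04d}"
                new_marker(mid, chrom, pos)
                qtl_truth.append({
                    "chrom": chrom, "start": s, "end": e, "category": cat,
                    "trait": trait, "left": mid, "right": None,
                    "expected_provenance": "one_marker_window", "planted_region": None,
                })
            else:
                length = int(round(math.exp(rng.uniform(log_lo, log_hi))))
                if length + 2 * pad >= L:
                    continue
                s = int(rng.integers(pad, L - length - pad + 1))
                e = s + length - 1
                if placer.in_zone(chrom, s - pad, e + pad):
                    continue
                if not (placer.amplicon_free(chrom, s) and placer.amplicon_free(chrom, e)):
                    continue
                lid, rid = f"M_Q{j:04d}_L", f"M_Q{j:04d}_R"
                new_marker(lid, chrom, s)
                new_marker(rid, chrom, e)
                qtl_truth.append({
                    "chrom": chrom, "start": s, "end": e, "category": cat,
                    "trait": trait, "left": lid, "right": rid,
                    "expected_provenance": "two_markers", "planted_region": None,
                })
            placed = True
            break
        if not placed:
            raise QtlAtlasError("could not place a background QTL; landscape too crowded")

    # ---- embed amplicons and verify primer uniqueness --------------------
    def embed(mid: str) -> None:
        t = marker_truth[mid]
        arr = arrays[t["chrom"]]
        s0 = t["pos"] - 1 - _HALF_AMP
        arr[s0 : s0 + _PRIMER_LEN] = np.frombuffer(t["fwd"].encode(), dtype=np.uint8)
        rc = revcomp(t["rev"]).encode()
        arr[s0 + _AMPLICON_LEN - _PRIMER_LEN : s0 + _AMPLICON_LEN] = np.frombuffer(rc, dtype=np.uint8)

    for mid in marker_truth:
        embed(mid)
    for _pass in range(100):
        counts = _kmer_counts(
            arrays.values(),
            {p for t in marker_truth.values()
             for p in (t["fwd"], revcomp(t["fwd"]), t["rev"], revcomp(t["rev"]))},
        )
        bad = []
        for mid, t in marker_truth.items():
            fwd, rev = t["fwd"], t["rev"]
            if not (counts[fwd] == 1 and counts[revcomp(fwd)] == 0
                    and counts[revcomp(rev)] == 1 and counts[rev] == 0):
                bad.append(mid)
        if not bad:
            break
        for mid in bad:
            marker_truth[mid]["fwd"] = _rand_primer(rng)
            marker_truth[mid]["rev"] = _rand_primer(rng)
            embed(mid)
    else:
        raise QtlAtlasError("primer uniqueness unattainable after 100 passes")

    genome = GenomeAssembly(
        name="synthetic", chromosomes=[(c, L) for c in chroms],
        sequences={c: arrays[c].tobytes().decode("ascii") for c in chroms},
    )

    # ---- provenance columns ----------------------------------------------
    studies = [f"S{i + 1}" for i in range(config.n_studies)]
    populations = [f"Pop{i + 1}" for i in range(config.n_studies)]
    countries = [config.countries[i % len(config.countries)] for i in range(config.n_studies)]
    qtl_rows: list[dict] = []
    manifest_qtls: dict[str, dict] = {}
    for i, t in enumerate(qtl_truth):
        qid = f"Q{i + 1:04d}"
        si = int(rng.integers(config.n_studies))
        row = {c: "" for c in QTL_TABLE_COLUMNS}
        row.update(qtl_id=qid, trait=t["trait"], study=studies[si],
                   population=populations[si], country=countries[si])
        lt = marker_truth[t["left"]]
        row.update(left_marker=t["left"], left_fwd=lt["fwd"], left_rev=lt["rev"])
        if t["right"]:
            rt = marker_truth[t["right"]]
            row.update(right_marker=t["right"], right_fwd=rt["fwd"], right_rev=rt["rev"])
        qtl_rows.append(row)
        manifest_qtls[qid] = {
            "chrom": t["chrom"], "start": int(t["start"]), "end": int(t["end"]),
            "category": t["category"], "trait": t["trait"], "study": studies[si],
            "population": populations[si], "country": countries[si],
            "expected_provenance": t["expected_provenance"],
            "planted_region": t["planted_region"],
        }

    # ---- genes ------------------------------------------------------------
    n_inside = int(round(config.n_genes * config.fraction_genes_in_regions)) if planted else 0
    genes: list[GeneRecord] = []
    planted_gene_region: dict[str, int] = {}
    strands = "+-"
    for gi in range(n_inside):
        region = planted[gi % len(planted)]
        span = region.end - region.start + 1
        glen = int(rng.integers(1000, min(4001, span)))
        s = int(rng.integers(region.start, region.end - glen + 2))
        gid = f"g{gi + 1:04d}"
        genes.append(GeneRecord(gid, region.chrom_id, s, s + glen - 1,
                                strands[int(rng.integers(2))]))
        planted_gene_region[gid] = gi % len(planted)
    for gi in range(n_inside, config.n_genes):
        gid = f"g{gi + 1:04d}"
        for _attempt in range(500):
            chrom = chroms[int(rng.integers(len(chroms)))]
            glen = int(rng.integers(1000, 4001))
            s = int(rng.integers(1, L - glen + 1))
            if placer.in_zone(chrom, s, s + glen - 1):
                continue
            genes.append(GeneRecord(gid, chrom, s, s + glen - 1,
                                    strands[int(rng.integers(2))]))
            break
        else:
            raise QtlAtlasError("could not place a background gene")
    order = {c: i for i, c in enumerate(chroms)}
    genes.sort(key=lambda g: (order[g.chrom_id], g.start, g.gene_id))

    # ---- interaction graph -------------------------------------------------
    node_ids = [g.gene_id for g in genes]
    g_seed = int(rng.integers(2**31 - 1))
    graph = nx.gnp_random_graph(len(node_ids), config.graph_edge_prob, seed=g_seed)
    graph = nx.relabel_nodes(graph, dict(enumerate(node_ids)))
    inside_ids = sorted(planted_gene_region)
    n_hubs = min(config.n_planted_hubs, len(inside_ids))
    hub_ids = [inside_ids[int(i)] for i in
               rng.choice(len(inside_ids), size=n_hubs, replace=False)] if n_hubs else []
    hub_target = min(config.hub_degree_target, len(node_ids) - 1)
    for hub in hub_ids:
        while graph.degree[hub] < hub_target:
            other = node_ids[int(rng.integers(len(node_ids)))]
            if other != hub and not graph.has_edge(hub, other):
                graph.add_edge(hub, other)
    edges = sorted(tuple(sorted(e)) for e in graph.edges)

    # ---- GO-slim mapping ----------------------------------------------------
    vocab = load_go_slim_vocabulary()
    go_mapping = {
        g.gene_id: vocab[int(rng.integers(len(vocab)))]
        for g in genes if rng.random() < config.go_mapped_fraction
    }

    manifest = {
        "seed": config.rng_seed,
        "config": _config_dict(config),
        "chromosomes": [[c, L] for c in chroms],
        "calibration": {"cm_to_bp": config.cm_to_bp, "window_cM": config.window_cM},
        "markers": marker_truth,
        "qtls": manifest_qtls,
        "planted_regions": [
            {"chrom": r.chrom_id, "start": r.start, "end": r.end,
             "categories": sorted(r.categories), "multiplicity": r.multiplicity,
             "n_qtls": r.n_qtls, "hot": r.hot}
            for r in planted
        ],
        "planted_candidate_genes": planted_gene_region,
        "planted_hubs": sorted(hub_ids),
        "graph": {"n_nodes": graph.number_of_nodes(), "n_edges": graph.number_of_edges()},
    }

    bundle = SyntheticBundle(
        config=config, genome=genome, marker_truth=marker_truth,
        qtl_rows=qtl_rows, genes=genes, edges=edges,
        go_mapping=go_mapping, manifest=manifest,
    )
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def _config_dict(config: SimConfig) -> dict:
    return asdict(config)


def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genome_fasta(bundle.genome, outdir / "genome.fa")
    with open(outdir / "chrom_sizes.tsv", "w") as fh:
        for chrom, length in bundle.genome.chromosomes:
            fh.write(f"{chrom}\t{length}\n")
    with open(outdir / "markers.tsv", "w") as fh:
        fh.write("marker_id\tfwd\trev\tchrom\tpos\n")
        for mid in sorted(bundle.marker_truth):
            t = bundle.marker_truth[mid]
            fh.write(f"{mid}\t{t['fwd']}\t{t['rev']}\t{t['chrom']}\t{t['pos']}\n")
    pd.DataFrame(bundle.qtl_rows, columns=QTL_TABLE_COLUMNS).to_csv(
        outdir / "qtls.tsv", sep="\t", index=False
    )
    write_genes_gff3(bundle.genes, outdir / "genes.gff3")
    with open(outdir / "edges.tsv", "w") as fh:
        for a, b in bundle.edges:
            fh.write(f"{a}\t{b}\n")
    with open(outdir / "go_slim.tsv", "w") as fh:
        for gid in sorted(bundle.go_mapping):
            fh.write(f"{gid}\t{bundle.go_mapping[gid]}\n")
    with open(outdir / "trait_catalog.tsv", "w") as fh:
        fh.write("trait\tcategory\n")
        for cat in CATEGORY_CODES:
            for trait in TRAIT_POOLS[cat]:
                fh.write(f"{trait}\t{cat}\n")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def perturb(bundle_dir, outdir, noise_bp: int = 0, drop_marker_rate: float = 0.0,
            seed: int = 0) -> None:
    """Degrade a written bundle: delete one flanking marker from
    ``drop_marker_rate`` of two-marker QTLs (forcing the single-marker window
    path) and/or jitter interval endpoints by +-``noise_bp``. Jittered QTLs
    are rewritten as pre-anchored coordinates (their markers cleared), since
    co-localized QTLs share embedded marker pairs that cannot be re-planted
    independently."""
    if noise_bp < 0:
        raise QtlAtlasError("noise_bp must be >= 0")
    if not (0.0 <= drop_marker_rate <= 1.0):
        raise QtlAtlasError("drop_marker_rate must be in [0, 1]")
    bundle_dir, outdir = Path(bundle_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(bundle_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    lengths = {c: l for c, l in manifest["chromosomes"]}
    rng = np.random.default_rng(seed)
    df = pd.read_csv(bundle_dir / "qtls.tsv", sep="\t", dtype=str).fillna("")
    for i in df.index:
        qid = df.at[i, "qtl_id"]
        truth = manifest["qtls"][qid]
        two = bool(df.at[i, "left_marker"]) and bool(df.at[i, "right_marker"])
        if two and rng.random() < drop_marker_rate:
            for col in ("right_marker", "right_fwd", "right_rev"):
                df.at[i, col] = ""
            continue
        if noise_bp > 0:
            L = lengths[truth["chrom"]]
            s = truth["start"] + int(rng.integers(-noise_bp, noise_bp + 1))
            e = truth["end"] + int(rng.integers(-noise_bp, noise_bp + 1))
            s, e = max(1, min(s, e)), min(L, max(s, e))
            for col in ("left_marker", "left_fwd", "left_rev",
                        "right_marker", "right_fwd", "right_rev"):
                df.at[i, col] = ""
            df.at[i, "chrom"] = truth["chrom"]
            df.at[i, "start"] = str(s)
            df.at[i, "end"] = str(e)
    for name in ("genome.fa", "chrom_sizes.tsv", "markers.tsv", "genes.gff3",
                 "edges.tsv", "go_slim.tsv", "trait_catalog.tsv"):
        if (bundle_dir / name).exists() and bundle_dir != outdir:
            shutil.copyfile(bundle_dir / name, outdir / name)
    df.to_csv(outdir / "qtls.tsv", sep="\t", index=False)
    manifest["perturb"] = {"noise_bp": noise_bp, "drop_marker_rate": drop_marker_rate,
                           "seed": seed}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
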