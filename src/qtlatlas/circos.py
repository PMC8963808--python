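"""Circos-format track export for the aligned map (file generation only).

One karyotype file, one QTL track per trait category — written in the map's
track order, innermost yield outward: Y, S, H, B, A — and one highlight file
for the overlap regions. Circos coordinates are 0-based half-open.
"""
from __future__ import annotations

from pathlib import Path

from .projection import QTLAtlas
from .regions import OverlapRegion

#: track order, innermost first
TRACK_ORDER = ("Y", "S", "H", "B", "A")

_KARYOTYPE_COLORS = {"A": "vdblue", "C": "vdgreen"}


def export_circos(atlas: QTLAtlas, regions: list[OverlapRegion], outdir,
                  min_categories: int = 2) -> dict[str, str]:
    """Write karyotype.txt, qtl_<cat>.txt per category and
    overlap_regions.txt; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    kpath = outdir / "karyotype.txt"
    with open(kpath, "w") as fh:
        for chrom, length in atlas.assembly.chromosomes:
            color = _KARYOTYPE_COLORS.get(chrom[:1].upper(), "grey")
            fh.write(f"chr - {chrom} {chrom} 0 {length} {color}\n")
    files["karyotype"] = str(kpath)

    for cat in TRACK_ORDER:
        tpath = outdir / f"qtl_{cat}.txt"
        with open(tpath, "w") as fh:
            for q in atlas.qtls:
                if q.category == cat:
                    fh.write(f"{q.chrom_id} {q.start - 1} {q.end} id={q.qtl_id}\n")
        files[f"track_{cat}"] = str(tpath)

    hpath = outdir / "overlap_regions.txt"
    with open(hpath, "w") as fh:
        for r in regions:
            if r.multiplicity >= min_categories:
                fh.write(f"{r.chrom_id} {r.start - 1} {r.end} id={r.region_id}\n")
    files["highlights"] = str(hpath)
    return files
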