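import json
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

from qtlatlas import (
    GenomeAssembly,
    PhysicalQTL,
    PipelineInputs,
    QTLAtlas,
    SimConfig,
    config_for_bundle,
    run_pipeline,
    simulate_landscape,
)
from qtlatlas.io import load_trait_catalog

settings.register_profile("suite", max_examples=25, derandomize=True, deadline=None)
settings.load_profile("suite")


# ----------------------------------------------------------- toy builders ----

def make_assembly(lengths: dict[str, int], sequences=None) -> GenomeAssembly:
    return GenomeAssembly(name="toy", chromosomes=list(lengths.items()),
                          sequences=sequences)


def make_qtl(qid, chrom, start, end, category="S", trait=None, study="S1",
             population="Pop1", country="China", provenance="preanchored"):
    traits = {"A": "drought tolerance", "B": "blackleg resistance",
              "H": "auxin content", "S": "oil content", "Y": "seed yield"}
    return PhysicalQTL(
        chrom_id=chrom, start=start, end=end, qtl_id=qid,
        trait_name=trait or traits[category], category=category,
        study_id=study, population=population, country=country,
        provenance=provenance,
    )


def make_atlas(qtls, lengths=None) -> QTLAtlas:
    if lengths is None:
        lengths = {}
        for q in qtls:
            lengths[q.chrom_id] = max(lengths.get(q.chrom_id, 1), q.end + 10)
    return QTLAtlas(assembly=make_assembly(lengths), qtls=list(qtls))


def random_landscape(rng: np.random.Generator, n_qtls=None, chrom_len=None,
                     point_fraction=0.1):
    """A random one-chromosome landscape for oracle-equivalence tests; trait
    names are drawn per category so trait-pair tests are meaningful."""
    trait_pool = {"A": ["drought tolerance", "heat tolerance"],
                  "B": ["blackleg resistance"],
                  "H": ["auxin content"],
                  "S": ["oil content", "protein content"],
                  "Y": ["seed yield", "plant height"]}
    cats = "ABHSY"
    if chrom_len is None:
        chrom_len = int(rng.integers(500, 10_001))
    if n_qtls is None:
        n_qtls = int(rng.integers(1, 61))
    qtls = []
    for i in range(n_qtls):
        s = int(rng.integers(1, chrom_len + 1))
        if rng.random() < point_fraction:
            e = s
        else:
            e = min(chrom_len, s + int(rng.integers(0, max(2, chrom_len // 3))))
        cat = cats[int(rng.integers(5))]
        trait = trait_pool[cat][int(rng.integers(len(trait_pool[cat])))]
        qtls.append(make_qtl(f"q{i}", "A1", s, e, cat, trait=trait))
    return make_atlas(qtls, {"A1": chrom_len}), chrom_len


def random_genome(rng: np.random.Generator, lengths: dict[str, int]) -> GenomeAssembly:
    seqs = {c: "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
            for c, n in lengths.items()}
    return make_assembly(lengths, seqs)


# --------------------------------------------------------------- fixtures ----

@pytest.fixture(scope="session")
def catalog():
    return load_trait_catalog()


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory) -> Path:
    """The default synthetic bundle (seed 42), written once per session."""
    d = tmp_path_factory.mktemp("bundle")
    simulate_landscape(SimConfig(rng_seed=42), d)
    return d


@pytest.fixture(scope="session")
def bundle_manifest(bundle_dir) -> dict:
    with open(bundle_dir / "manifest.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def pipeline_run(bundle_dir, tmp_path_factory):
    """Full pipeline executed once on the default bundle."""
    outdir = tmp_path_factory.mktemp("pipeline_out")
    report = run_pipeline(PipelineInputs.from_bundle(bundle_dir),
                          config_for_bundle(bundle_dir), outdir)
    return report, outdir
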