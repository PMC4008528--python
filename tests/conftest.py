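"""Shared fixtures: a small synthetic dataset and calibrated recognizers.

Everything is generated programmatically; the recognizers are built once
per session from the packaged seed alignments.
"""
from __future__ import annotations

import numpy as np
import pytest

from comcensus.census import build_recognizers
from comcensus.synth import SynthConfig, seed_msas, simulate


@pytest.fixture(scope="session")
def recognizers():
    """Calibrated profile HMMs for the four roles + ComP sub-domains."""
    return build_recognizers(seed_msas(), seed=0, n_null=500)


@pytest.fixture(scope="session")
def small_dataset():
    """Eight genomes (4 per clade), default study conditions."""
    return simulate(SynthConfig(n_genomes_per_clade=4, seed=13))


@pytest.fixture(scope="session")
def census_dataset():
    """The census-scale dataset: 50 genomes per clade, divergence 0.1."""
    return simulate(SynthConfig(n_genomes_per_clade=50, seed=2601))


@pytest.fixture(scope="session")
def census_result(census_dataset, recognizers):
    """Full census over the 100-genome dataset plus decoy-only genomes."""
    from comcensus.genome_io import AnnotatedGenome
    from comcensus.census import scan_genomes
    from comcensus.synth import make_decoys, random_dna

    decoy_only = []
    for i in range(10):
        rng = np.random.default_rng(40_000 + i)
        g = AnnotatedGenome(genome_id=f"decoyonly{i:02d}",
                            contigs={f"decoyonly{i:02d}_c1": random_dna(300, rng)})
        decoy_only.append(make_decoys(g, 6, rng))
    genomes = list(census_dataset.genomes) + decoy_only
    loci, audit, n = scan_genomes(genomes, recognizers)
    return {"loci": loci, "audit": audit, "n_proteins": n,
            "decoy_ids": {g.genome_id for g in decoy_only}}
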