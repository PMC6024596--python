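"""Shared fixtures: a small synthetic genus for the alignment-heavy
stages and a full-size reference genome for mapping/QC stages."""

import pytest

from phagesig import (
    ScoringScheme,
    SimConfig,
    generate_genus_and_outgroups,
    generate_reference,
    simulate_metagenome,
)


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def small_genus():
    """Genus of 10 short genes: 2 close relatives, 1 distant (d=0.25),
    2 outgroups sharing gp02/gp05 at d=0.02 (planted uninformative)."""
    cfg = SimConfig(seed=3, n_genes=10, gene_len_mean=240, gene_len_sd=30,
                    divergence_list=(0.01, 0.02, 0.25),
                    outgroup_shared_genes=("gp02", "gp05"),
                    outgroup_shared_divergence=0.02)
    genomes, truth = generate_genus_and_outgroups(cfg)
    return cfg, genomes, truth


@pytest.fixture(scope="session")
def small_parts(small_genus):
    cfg, genomes, truth = small_genus
    ref = genomes[0]
    relatives = [g for g in genomes if g.id.startswith("relative")]
    outgroups = [g for g in genomes if g.id.startswith("outgroup")]
    return ref, relatives, outgroups, truth


@pytest.fixture(scope="session")
def big_reference():
    """Full-size (~66 Kbp, 90 CDS) reference genome."""
    cfg = SimConfig(seed=5)
    ref, _ = generate_reference(cfg)
    return cfg, ref


@pytest.fixture(scope="session")
def reads_15x(big_reference):
    cfg, ref = big_reference
    return simulate_metagenome([ref], [15.0], cfg, seed=11)
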