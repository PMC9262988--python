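"""Shared fixtures: all synthetic, generated at session scope."""

import numpy as np
import pytest

import coreprof as cp


@pytest.fixture(scope="session")
def tiny_taxonomy():
    # 1 phylum, 2 genera x 3 species = 6 species
    return cp.make_taxonomy(n_phyla=1, genera_per_phylum=2, species_per_genus=3)


@pytest.fixture(scope="session")
def tiny_db(tiny_taxonomy):
    # small gene panel keeps index builds fast; divergence 0.05 gives sibling
    # species distinguishable but related sequences
    return cp.generate_core_genes(
        tiny_taxonomy,
        genes_per_species=12,
        gene_length_range=(300, 500),
        divergence=0.05,
        seed=101,
    )


@pytest.fixture(scope="session")
def tiny_index(tiny_db):
    return cp.build_kmer_index(tiny_db, k=35)


@pytest.fixture(scope="session")
def tiny_community(tiny_db):
    species = tiny_db.species_ids()[:3]
    return cp.simulate_community(species, [0.5, 0.3, 0.2], seed=7)


@pytest.fixture(scope="session")
def tiny_reads(tiny_community, tiny_db):
    cfg = cp.ReadSimConfig(n_reads=3000, substitution_error_rate=0.0, seed=11)
    return cp.simulate_reads(tiny_community, tiny_db, cfg)


@pytest.fixture(scope="session")
def full_db(tiny_taxonomy):
    """Full-size gene panel (92 genes/species) for end-to-end checks."""
    return cp.generate_core_genes(
        tiny_taxonomy,
        genes_per_species=92,
        gene_length_range=(500, 1000),
        divergence=0.05,
        seed=1,
    )


@pytest.fixture(scope="session")
def full_index(full_db):
    return cp.build_kmer_index(full_db, k=35)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
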