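"""Shared fixtures: the default synthetic suite and its analysis products.

The heavier stages (clustering, IS discovery, census, HGT scan) are computed
once per session and reused by the module tests and the acceptance tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from mobilomics.hgt import cross_species_regions
from mobilomics.insertion_sequences import ISElement, build_is_library, is_census
from mobilomics.pangenome import build_profile
from mobilomics.simulate import (
    GenomePoolSpec,
    ISSpec,
    SimulationConfig,
    default_suite,
    simulate_genome_set,
)

SUITE_SEED = 1


@pytest.fixture(scope="session")
def suite():
    genomes, ledger = simulate_genome_set(default_suite(seed=SUITE_SEED))
    return genomes, ledger


@pytest.fixture(scope="session")
def recipients(suite):
    genomes, _ = suite
    return [g for g in genomes if g.species_label == "SpeciesA"]


@pytest.fixture(scope="session")
def donors(suite):
    genomes, _ = suite
    return [g for g in genomes if g.species_label != "SpeciesA"]


@pytest.fixture(scope="session")
def pan_profile(recipients):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # CDS-without-translation warnings
        return build_profile(recipients)


@pytest.fixture(scope="session")
def is_results(suite):
    genomes, _ = suite
    library, lib_copies = build_is_library(genomes)
    full, partial, census_copies = is_census(library, genomes)
    return {
        "library": library,
        "full": full,
        "partial": partial,
        "copies": census_copies,
    }


@pytest.fixture(scope="session")
def hgt_regions(recipients, donors):
    regions = []
    for g in recipients:
        regions.extend(cross_species_regions(g, donors))
    return regions


@pytest.fixture(scope="session")
def noise_census():
    """IS census under 5% per-copy substitution noise.

    The census query is the planted element consensus from the ledger: two
    independently 5%-mutated copies sit right at the 90% identity floor
    against each other, while copy-vs-consensus identity is ~95%.
    """
    genomes, ledger = simulate_genome_set(
        default_suite(seed=SUITE_SEED, is_copy_divergence=0.05)
    )
    library = [
        ISElement(
            name=name,
            source_genome="consensus",
            transposase_locus=("consensus", name),
            transposase_translation="",
            boundaries=(0, info["length"]),
            element_sequence=info["sequence"],
            left_ir=info["ir"],
            right_ir=info["ir"],
        )
        for name, info in ledger.is_elements.items()
    ]
    full, partial, census_copies = is_census(library, genomes)
    return {"ledger": ledger, "full": full, "partial": partial, "copies": census_copies}


@pytest.fixture()
def tiny_config():
    """A fast 3-genome configuration for pipeline-level tests."""
    return SimulationConfig(
        recipients=GenomePoolSpec(
            strains=["T1", "T2", "T3"],
            species="SpA",
            core_genes=25,
            shell_genes=6,
            orfans_per_genome=4,
            chromosome_length=120_000,
        ),
        donors=[
            GenomePoolSpec(
                strains=["TD"], species="SpB", core_genes=20, chromosome_length=60_000
            )
        ],
        is_specs=[
            ISSpec(
                name="E1",
                element_length=1000,
                ir_length=14,
                copies_per_genome={"T1": (2, 2), "T2": (2, 3), "T3": (2, 2)},
                in_gene_fraction=0.3,
            )
        ],
        seed=7,
    )


def match_intervals(planted, detected, tol):
    """Greedy one-to-one matching of (genome, start, end) intervals."""
    remaining = list(detected)
    matched = 0
    for g, s, e in planted:
        hit = next(
            (
                d
                for d in remaining
                if d[0] == g and abs(d[1] - s) <= tol and abs(d[2] - e) <= tol
            ),
            None,
        )
        if hit is not None:
            matched += 1
            remaining.remove(hit)
    return matched


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
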