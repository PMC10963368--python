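"""Shared fixtures.

The ``index_convention`` fixture asserts the package-wide coordinate
convention — 1-based, inclusive residue/codon indices with residue i of
a protein corresponding to codon i of its ORF — on a tiny generated
dataset, and is pulled into every module's tests.
"""

import numpy as np
import pytest
from hypothesis import settings

from cotrans.datatypes import FootprintProfile
from cotrans.energetics import aggregate_replicates
from cotrans.synthetic import (
    EnergySimSpec,
    SerpSimSpec,
    ToyComplexSpec,
    gen_energy_table,
    gen_footprint_profiles,
    gen_toy_complex,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def index_convention():
    """Assert the shared 1-based residue==codon convention, then hand the
    checked toy dataset to the test."""
    # codon 3 of a 10-codon ORF lives at counts[2]
    profile = FootprintProfile(
        orf_id="toy", sample_kind="translatome", replicate_id=1,
        counts=np.eye(10, dtype=int)[2] * 7, total_mapped_reads=100,
    )
    assert profile.counts[3 - 1] == 7 and profile.length == 10

    # residue 5 of a 10-residue subunit is row residue_index == 5
    table, truth = gen_energy_table(
        EnergySimSpec(n_residues=10, clusters=[(5, 5, -4.0)], noise_sd=0.0)
    )
    aggregate_replicates(table)
    assert table.mean_by_residue()[5] == -4.0
    assert truth["cluster_members"] == {5}
    return {"profile": profile, "table": table}


@pytest.fixture
def serp_spec():
    return SerpSimSpec(
        orf_length_codons=600, onset_codon=104, enrichment_fold=300.0,
        baseline_depth=50.0, library_size=10_000_000, n_replicates=2, seed=0,
    )


@pytest.fixture
def small_serp_profiles():
    spec = SerpSimSpec(
        orf_length_codons=120, onset_codon=40, enrichment_fold=50.0,
        baseline_depth=20.0, library_size=1_000_000, n_replicates=2, seed=11,
    )
    profiles = gen_footprint_profiles(spec)
    trans = [p for p in profiles if p.sample_kind == "translatome"]
    inter = [p for p in profiles if p.sample_kind == "interactome"]
    return spec, trans, inter


@pytest.fixture
def clustered_table():
    """178-residue subunit with one planted hotspot cluster (60-69 at -8)."""
    spec = EnergySimSpec(
        n_residues=178, clusters=[(60, 69, -8.0)], background_mean=0.0,
        noise_sd=0.25, n_replicates=3, seed=7,
    )
    table, truth = gen_energy_table(spec)
    return aggregate_replicates(table), truth


@pytest.fixture
def toy_complex():
    spec = ToyComplexSpec(
        n_residues_chain_a=12, n_residues_chain_b=12,
        interface_pairs=[(6, 6, 3.9)], fluctuation_amplitudes=0.4,
        n_frames=50, seed=3,
    )
    structure, traj = gen_toy_complex(spec)
    return spec, structure, traj
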