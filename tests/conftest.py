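"""Shared fixtures: session-scoped synthetic datasets with planted truth."""

from __future__ import annotations

import warnings

import pytest

from strscape.io_formats import StrscapeWarning
from strscape.synthetic_data import DomainFamilyConfig, SimulationConfig, simulate


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """Moderate full-featured dataset: STRs, genes, GO, variants, domains.

    Generated under warnings-as-errors so every emitted file is clean.
    Returns (PlantedTruth, out_dir).
    """
    out = tmp_path_factory.mktemp("sim_default")
    cfg = SimulationConfig(seed=7, n_contigs=4, contig_length_bp=100_000, n_genes=120)
    with warnings.catch_warnings():
        warnings.simplefilter("error", StrscapeWarning)
        truth = simulate(cfg, out)
    return truth, out


@pytest.fixture(scope="session")
def census_sim(tmp_path_factory):
    """Small dataset tuned for the domain census: 15 copies, 3 pseudogenized."""
    out = tmp_path_factory.mktemp("sim_census")
    cfg = SimulationConfig(
        seed=11,
        n_contigs=1,
        contig_length_bp=30_000,
        str_spectrum={2: 40_000, 3: 12_000},  # feasible targets at this genome size
        n_genes=0,
        n_go_terms=0,
        enriched_terms={},
        tri_indel_fraction=0.0,
        variant_rates={},
        domain_families=[
            DomainFamilyConfig(
                name="FISNA-like",
                n_copies=15,
                length_aa=72,
                pseudogene_fraction=0.2,
                collapse_multiplicities=[],
                flank_bp=900,
            )
        ],
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", StrscapeWarning)
        truth = simulate(cfg, out)
    return truth, out
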