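"""Shared fixtures: all data are generated programmatically at test time.

Session-scoped fixtures hold the default-condition simulation (one
200 kb genome, its reference placement configuration, a clonal digest,
and the deeper population library) so the expensive pieces are built
once and shared across test modules.
"""

import warnings

import numpy as np
import pandas as pd
import pytest

from hypernuc.genome_io import GenomeSeq, coverage
from hypernuc.simulate import (
    SimConfig,
    simulate_digest,
    simulate_ev,
    simulate_expression,
    simulate_genome,
    simulate_library,
    simulate_placements,
    tss_true_occupancy,
)

warnings.filterwarnings("ignore", message=".*fragments are >= 160 bp.*")


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition simulation, seed 1: genome + annotation + placements."""
    cfg = SimConfig(seed=1)
    genome, genes, promoters, tss = simulate_genome(cfg)
    placements, true_occ = simulate_placements(genome, cfg)
    return {
        "config": cfg,
        "genome": genome,
        "genes": genes,
        "promoters": promoters,
        "tss": tss,
        "placements": placements,
        "true_occ": true_occ,
    }


@pytest.fixture(scope="session")
def clonal_digest(default_sim):
    """Single-configuration digest (mu = 20) plus a depth-matched EV control."""
    cfg = default_sim["config"]
    frags = simulate_digest(default_sim["placements"], default_sim["genome"], cfg)
    ev = simulate_ev(default_sim["genome"], cfg, n_fragments=len(frags))
    return {"fragments": frags, "ev": ev}


@pytest.fixture(scope="session")
def population_library(default_sim):
    """Default-depth population library (300 cells, 400k fragments) + EV."""
    cfg = default_sim["config"]
    lib = simulate_library(default_sim["genome"], cfg)
    ev = simulate_ev(default_sim["genome"], cfg)
    return {"library": lib, "ev": ev, "ev_cov": coverage(ev, default_sim["genome"])}


@pytest.fixture(scope="session")
def default_expression(default_sim):
    """Occupancy-coupled DE tables and compendium for the default simulation."""
    return simulate_expression(
        tss_true_occupancy(default_sim["true_occ"], default_sim["tss"]),
        default_sim["config"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_genome():
    """Small deterministic two-contig genome (one linear, one circular)."""
    rs = np.random.default_rng(7)
    seq = "".join(rs.choice(list("ACGT"), size=3000))
    return GenomeSeq(
        {"circ": seq, "lin": seq[:2000]},
        {"circ": True, "lin": False},
    )
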