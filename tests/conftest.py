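"""Shared fixtures: the simulation study and small reusable cohorts.

The recovery study simulates cohorts of coding loci under several selection
scenarios at a reduced scale (N=250 diploids, 200 codons, mu=8e-6, 4000
observed generations after a 1500-generation equilibration, 200 loci per
cohort, 20 replicate cohorts per scenario). Only estimator behaviour is
asserted downstream, so the absolute divergence scale is immaterial.
"""

import numpy as np
import pytest

from vipadapt.divergence_polymorphism import default_bin_edges
from vipadapt.synthetic_data import (
    CohortConfig,
    LocusConfig,
    bottleneck_schedule,
    generate_gene_cohort,
    scenario_mix,
    simulate_cohort,
)

POP = 250
CODONS = 200
MU = 8e-6
GENS = 4000
BURN = 1500
SAMPLE = 100
LOCI = 200
REPS = 20
BIN_EDGES = default_bin_edges(0.05)

RECOVERY_SCENARIOS = {
    "adaptive": dict(mix="adaptive", schedule=None, seed0=1000),
    "adaptive_weakdel": dict(mix="adaptive_weakdel", schedule=None, seed0=2000),
    "adaptive_weakdel_bottleneck": dict(
        mix="adaptive_weakdel",
        schedule=bottleneck_schedule(POP, BURN, GENS),
        seed0=3000,
    ),
    "purifying": dict(mix="purifying", schedule=None, seed0=4000),
}


def study_config(mix: str, schedule=None) -> LocusConfig:
    return LocusConfig(
        n_codons=CODONS, pop_size=POP, n_generations=GENS, mu=MU,
        burn_in=BURN, sample_n=SAMPLE,
        mutation_mix=scenario_mix(mix, POP),
        size_schedule=schedule,
    )


@pytest.fixture(scope="session")
def recovery_study():
    """Replicate cohorts per scenario: list of aggregated SimOutcome."""
    out = {}
    for name, spec in RECOVERY_SCENARIOS.items():
        cfg = study_config(spec["mix"], spec["schedule"])
        out[name] = [
            simulate_cohort(cfg, LOCI, seed=spec["seed0"] + r)[0]
            for r in range(REPS)
        ]
    return out


@pytest.fixture(scope="session")
def default_cohort():
    """A mid-size gene cohort with the default (paper-scale) VIP effects."""
    return generate_gene_cohort(CohortConfig(n_genes=3000, seed=17))


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no VIP effect on any quantity."""
    return generate_gene_cohort(CohortConfig.null(n_genes=1200, seed=23))
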