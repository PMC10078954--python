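"""Shared fixtures: a small three-primer cohort with a true twofold
circRNA deficit, its simulated Ct table and a fitted posterior (session
scoped — fitting is the expensive step and several suites reuse it)."""

import warnings

import pytest

from circqpcr import model, simulate
from circqpcr.types import CohortDesign, GenotypeGroup, PrimerInfo, PrimerMap


@pytest.fixture(scope="session")
def small_primer_map() -> PrimerMap:
    return PrimerMap(
        [
            PrimerInfo("Gapdh", "reference", "Gapdh"),
            PrimerInfo("circT", "circular", "HostG", paired_canonical="linT"),
            PrimerInfo("linT", "linear", "HostG"),
        ]
    )


@pytest.fixture(scope="session")
def small_design(small_primer_map) -> CohortDesign:
    # unbalanced sequencing-cohort shape: 6 hom (4M/2F) vs 4 wt (2M/2F)
    return CohortDesign(
        genotypes=[GenotypeGroup("wt", 4, 2, 2), GenotypeGroup("hom", 6, 4, 2)],
        n_litters=3,
        n_runs=2,
        primers=small_primer_map,
        replicates_per_well=3,
    )


@pytest.fixture(scope="session")
def small_truth(small_primer_map):
    # +1 cycle on the circular primer in hom at efficiency 2 => true Q = 0.5
    return simulate.default_truth(small_primer_map)


@pytest.fixture(scope="session")
def small_ct(small_design, small_truth):
    df, _ = simulate.simulate_ct_dataset(small_design, small_truth, seed=42)
    return df


@pytest.fixture(scope="session")
def fitted_small(small_ct):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(small_ct, seed=7, chains=2, draws=400, warmup=300)
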