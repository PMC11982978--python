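import numpy as np
import pandas as pd
import pytest

from dockscreen import (CountTable, DSiteLibrary, ScreenModel,
                        SimulationConfig, assign_fitness,
                        build_synthetic_library, simulate_selection)

# Printed variant sequences from the published competitive-kinase IC50 table
# (ISG20 docking peptide and its point mutants / insertions).
TABLE2_PEPTIDES = {
    "WT": "IRARRGLPRLAVSD",
    "I1N": "NRARRGLPRLAVSD",
    "R4A": "IRAARGLPRLAVSD",
    "R5A": "IRARAGLPRLAVSD",
    "I1R/R2I": "RIARRGLPRLAVSD",
    "G2+": "IGRARRGLPRLAVSD",
    "G7+": "IRARRGGLPRLAVSD",
    "G6Q": "IRARRQLPRLAVSD",
}

#: Published IC50 means (uM) for the ISG20 WT peptide against each kinase
#: variant, with 95% CIs from three replicates.
TABLE2_WT_ROW = {
    "WT": (5.4, 4.8, 6.2),
    "R133K": (220.0, 198.0, 253.0),
    "D319N": (230.0, 187.0, 290.0),
    "E320K": (330.0, 270.0, 399.0),
}


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_members=40, frac_heptp=0.2, seed=3,
                            read_depth=5000, n_replicates=2)


@pytest.fixture(scope="session")
def small_library(small_config):
    return build_synthetic_library(small_config)


@pytest.fixture(scope="session")
def small_fitness(small_config, small_library):
    return assign_fitness(small_library, small_config)


@pytest.fixture(scope="session")
def small_table(small_config, small_library, small_fitness):
    return simulate_selection(small_library, small_fitness, small_config)


@pytest.fixture(scope="session")
def small_scores(small_table):
    return ScreenModel(small_table).fit()


def make_count_table(counts: dict, doublings, genotype="WT",
                     condition="selective", replicate=1) -> CountTable:
    """Hand-built single-screen count table.

    ``counts`` maps member_id -> per-timepoint counts aligned with
    ``doublings``.
    """
    sids = [f"{genotype}_{condition}_r{replicate}_d{d:g}" for d in doublings]
    mat = pd.DataFrame(counts, index=sids).T
    mat.index.name = "member_id"
    samples = pd.DataFrame({
        "genotype": genotype, "condition": condition,
        "replicate": replicate, "doublings": list(doublings)}, index=sids)
    samples.index.name = "sample_id"
    return CountTable(mat, samples)
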