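import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None,
                          database=None)
settings.load_profile("deterministic")

from phylosym import (AbundanceTable, HostTree, SampleMetadata, SimConfig,
                      TaxonomyMap, simulate_dataset)


@pytest.fixture
def small_table():
    """3 samples x 4 ASVs of counts."""
    df = pd.DataFrame(
        [[5, 3, 0, 2], [1, 1, 1, 1], [0, 8, 2, 0]],
        index=["s1", "s2", "s3"],
        columns=["t1", "t2", "t3", "t4"],
        dtype=float,
    )
    return AbundanceTable(df, rank="ASV")


@pytest.fixture
def small_taxonomy():
    df = pd.DataFrame(
        {
            "phylum": ["p1", "p1", "p2", "p2"],
            "order": ["o1", "o1", "o2", "o3"],
            "genus": ["g1", "g2", "g3", "g4"],
        },
        index=["t1", "t2", "t3", "t4"],
    )
    return TaxonomyMap(df)


@pytest.fixture
def small_metadata():
    df = pd.DataFrame(
        {
            "host_species": ["spA", "spA", "spB"],
            "body_site": ["gut", "gut", "gut"],
        },
        index=["s1", "s2", "s3"],
    )
    return SampleMetadata(df)


@pytest.fixture
def three_taxon_tree():
    return HostTree.from_newick("((A:1,B:1):1,C:2);", is_path=False)


@pytest.fixture(scope="session")
def sim_small():
    """One small synthetic study shared across tests (8 species, 2 sites)."""
    cfg = SimConfig(n_species=8, n_taxa=40, n_sites=2,
                    samples_per_species_site=2, phi=0.8, depth=2000, seed=11)
    return simulate_dataset(cfg)
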