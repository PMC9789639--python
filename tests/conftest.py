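import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from aromdeg import (
    AbundanceMatrix,
    CommunityConfig,
    Pathway,
    PathwayCatalog,
    Reaction,
    build_abundance_matrix,
    hellinger,
    normalize_per_million,
    simulate_community,
    tmm_factors,
)


@pytest.fixture(scope="session")
def default_community():
    """Default synthetic community, seed 1: (genes, meta, truth)."""
    return simulate_community(CommunityConfig(seed=1))


@pytest.fixture(scope="session")
def default_matrices(default_community):
    """(raw, per-million, hellinger) EC matrices of the default community."""
    genes, meta, _ = default_community
    raw = build_abundance_matrix(genes, meta, "EC")
    lib = meta.set_index("sample_id")["library_reads"]
    factors = tmm_factors(raw, lib)
    pm = normalize_per_million(raw, lib, factors)
    return raw, pm, hellinger(pm)


@pytest.fixture
def toy_matrix():
    data = pd.DataFrame(
        {
            "s1": [2.0, 0.0, 1.0],
            "s2": [1.0, 3.0, 0.0],
            "s3": [0.5, 0.5, 4.0],
        },
        index=["e1", "e2", "e3"],
    )
    return AbundanceMatrix(data, state="raw_copies")


@pytest.fixture
def small_catalog():
    """Hand-built catalog exercising marker priorities and shared ECs."""
    return PathwayCatalog(
        [
            Pathway(
                "PWY_A",
                "vanillate funneling",
                "funneling",
                reactions=[
                    Reaction("A1", "1.1.1.1", ("ring-opening",), "K00001"),
                    Reaction("A2", "2.2.2.2", ("other",), "K00002"),
                ],
            ),
            Pathway(
                "PWY_B",
                "gentisate ring fission",
                "ring_fission",
                reactions=[
                    Reaction("B1", "3.3.3.3", ("ring-oxidation",), "K00003"),
                    Reaction("B2", "2.2.2.2", ("other",), "K00002"),
                ],
            ),
            Pathway(
                "PWY_C",
                "benzoate funneling",
                "funneling",
                reactions=[
                    Reaction("C1", "4.4.4.4", ("CoA-addition",), "K00004"),
                    Reaction("C2", "5.5.5.5", ("other",), "K00005"),
                ],
            ),
        ]
    )
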