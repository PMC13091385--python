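import numpy as np
import pandas as pd
import pytest

from ssptrace import SyntheticSpec, generate_lineage_collection, make_reference_queries
from ssptrace.io import RunConfig


def small_spec(seed: int = 0) -> SyntheticSpec:
    """A reduced collection (3 lineages, 3 families) for fast end-to-end tests."""
    lineages = ("TSAR", "Amoebozoa", "Obazoa")
    families = ("CEP", "PSY", "PEP")
    motifs = {
        "CEP": "DFRPTTPGHSPGVGH",
        "PSY": "DYGDPSANPKHDPGVG",
        "PEP": "ATKVKAKQRGKEKVSSGRPGQHN",
    }
    plan = pd.DataFrame(
        [[1, 1, 0], [1, 0, 1], [0, 1, 1]], index=list(lineages), columns=list(families)
    )
    return SyntheticSpec(
        lineages=lineages,
        families=families,
        motifs=motifs,
        decoys_per_lineage=30,
        positives_per_cell=6,
        presence_plan=plan,
        rng_seed=seed,
    )


@pytest.fixture(scope="session")
def small_run():
    """One deterministic small collection plus its reference queries."""
    spec = small_spec()
    collections, truth = generate_lineage_collection(spec)
    queries = make_reference_queries(spec)
    return spec, collections, truth, queries


@pytest.fixture()
def config():
    return RunConfig(rng_seed=0, profile_null_draws=200)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
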