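import pytest

from wcnp.chem_profile import AlkaneLadder, Component, ComponentTable
from wcnp.enrichment import GeneSetCollection
from wcnp.gene_sets import GeneSet
from wcnp.synthetic_data import Bundle, SimConfig, generate
from wcnp.weighting import TargetMap


@pytest.fixture
def ladder() -> AlkaneLadder:
    return AlkaneLadder(((10, 10.0), (11, 12.0), (12, 14.5), (13, 18.0), (14, 21.0)))


@pytest.fixture
def toy_table() -> ComponentTable:
    return ComponentTable(
        (
            Component("alpha", "100-00-0", retention_time=10.5, area_pct=50.0,
                      oral_bioavailability=0.8),
            Component("beta", "200-00-0", retention_time=13.0, area_pct=30.0,
                      oral_bioavailability=0.5),
            Component("gamma", "300-00-0", retention_time=19.0, area_pct=20.0,
                      oral_bioavailability=0.1),
        )
    )


@pytest.fixture
def toy_edges() -> TargetMap:
    return TargetMap.from_pairs(
        [("alpha", "T1"), ("beta", "T1"), ("beta", "T2"), ("gamma", "T3")]
    )


@pytest.fixture
def toy_collection() -> GeneSetCollection:
    return GeneSetCollection.from_sets(
        {
            "P1": ("both scored targets", frozenset({"T1", "T2", "T9"})),
            "P2": ("one scored target", frozenset({"T3", "T8"})),
            "P3": ("no scored target", frozenset({"T7", "T8", "T9"})),
        },
        universe=frozenset({f"T{i}" for i in range(1, 10)}),
    )


@pytest.fixture(scope="session")
def default_bundle() -> Bundle:
    """One generated bundle shared across tests (seed 7, stated defaults)."""
    return generate(SimConfig(seed=7))
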