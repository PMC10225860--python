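import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from siicov.grid import GridSpec
from siicov.ingest import AnnualPresence
from siicov.taxonomy import build_synonym_table

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def table():
    """Small synonym fixture: two accepted species with one variant each."""
    return build_synonym_table(
        [
            ("Nesomys rufus", "Nesomys rufus", "mammal"),
            ("Nesomys audeberti rufus", "Nesomys rufus", "mammal"),
            ("Brachypteracias leptosomus", "Brachypteracias leptosomus", "bird"),
            ("Brachypteracias leptosomes", "Brachypteracias leptosomus", "bird"),
        ]
    )


@pytest.fixture
def grid10():
    """10x10 grid of 110 km cells with its origin at the projected origin."""
    return GridSpec("cea_sphere_30", 110_000.0, 0.0, 0.0, 10, 10)


def make_presence(grid, triples, source="occ"):
    return AnnualPresence(grid.key(), source, frozenset(triples))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
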