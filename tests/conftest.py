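import pytest

from fentonflux.metabolic_map import MetabolicMap, ReactionModule, default_map


@pytest.fixture(scope="session")
def iron_map():
    return default_map()


@pytest.fixture()
def chain_map():
    """A -> R1 -> B -> R2 -> C with B balanced."""
    return MetabolicMap(
        metabolites=["A", "B", "C"],
        modules=[
            ReactionModule("R1", ["G1", "G2"], consumes=[], produces=["B"]),
            ReactionModule("R2", ["G3", "G4"], consumes=["B"], produces=["C"]),
        ],
        balanced_set=["B"],
    )
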