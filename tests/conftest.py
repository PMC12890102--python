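import pytest

from panshrna import FamilySimSpec, MatchModel, PlantedWindow, simulate_family

# The five validated 22-nt histone target sites (mRNA sense, 5'->3').
HISTONE_TARGETS = {
    "H1": "TTGGGCTTCACCGCCTTTGCCT",
    "H2A": "ATGCGCGTCTTCTTGTTGTCGC",
    "H2B": "TTGACGAACGAGTTCATGATGC",
    "H3": "TTGGTGTCCTCGAAGAGCCCCA",
    "H4": "TAGACCACGTCCATGGCCGTGA",
}


@pytest.fixture(scope="session")
def histone_targets():
    return dict(HISTONE_TARGETS)


@pytest.fixture
def default_model():
    return MatchModel()


@pytest.fixture
def planted_family():
    """8 isoforms, 10% divergence, with the H2B target planted at full coverage."""
    spec = FamilySimSpec(
        n_isoforms=8,
        length=400,
        per_site_divergence=0.10,
        planted_windows=(PlantedWindow(HISTONE_TARGETS["H2B"]),),
        seed=11,
        name="h2b_like",
    )
    return simulate_family(spec)
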