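import pytest

from grassbarcode import collapse_all, generate_fixture

EIGHT_SPECIES = [
    "Agr_cris_cristatum",
    "Bro_inermis",
    "Ely_dahuricus",
    "Ely_sibiricus",
    "Elt_repens",
    "Fes_rubra",
    "Ley_chinensis",
    "Lol_per_MedalistGold",
]

AGROPYRON = [
    "Agr_cris_cristatum",
    "Agr_cris_pectiniforme",
    "Agr_mongolicum",
    "Agr_desertorum",
]

LOLIUM_CULTIVARS = [
    "Lol_per_MedalistGold",
    "Lol_per_Pickwick",
    "Lol_per_Taya",
    "Lol_per_Ascend",
]


@pytest.fixture(scope="session")
def fixture_panel():
    """The deterministic 14-accession, 4-marker panel plus aligned blocks."""
    return generate_fixture(seed=1)


@pytest.fixture(scope="session")
def panel(fixture_panel):
    return fixture_panel[0]


@pytest.fixture(scope="session")
def blocks(fixture_panel):
    return fixture_panel[1]


@pytest.fixture(scope="session")
def assignments(panel):
    """Haplotype assignments for all four markers, composite-code order."""
    return collapse_all(panel)
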