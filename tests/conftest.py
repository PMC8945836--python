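import numpy as np
import pytest

from bulkmap.finemap import MarkerPanel

# Worked-example marker ladder: M1 and M9 at their published physical
# positions; inner positions invented (only marker identities are asserted),
# with the M5-M7 span set to the published 304.7 kb interval width.
PANEL_POSITIONS = {
    "M1": 1_499_657,
    "M2": 2_200_000,
    "M3": 3_000_000,
    "M4": 3_600_000,
    "M5": 4_100_000,
    "M6": 4_250_000,
    "M7": 4_404_700,
    "M8": 4_800_000,
    "M9": 5_194_567,
}

# Published per-marker recombinant counts among 1,524 mutant-class plants.
RECOMBINANT_COUNTS = {
    "M1": 55,
    "M2": 15,
    "M3": 6,
    "M4": 4,
    "M5": 2,
    "M6": 0,
    "M7": 9,
    "M8": 17,
    "M9": 21,
}

N_FINEMAP_INDIVIDUALS = 1524


@pytest.fixture(scope="session")
def paper_panel() -> MarkerPanel:
    names = tuple(sorted(PANEL_POSITIONS, key=PANEL_POSITIONS.get))
    return MarkerPanel(
        names, "A03", tuple(PANEL_POSITIONS[n] for n in names)
    )


@pytest.fixture(scope="session")
def finemap_fixture(paper_panel):
    from bulkmap.simpop import make_finemap_fixture

    return make_finemap_fixture(
        RECOMBINANT_COUNTS, N_FINEMAP_INDIVIDUALS, paper_panel, seed=11
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
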