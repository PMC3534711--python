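import numpy as np
import pandas as pd
import pytest

from woodfall.community_stats import TagTable
from woodfall.core_io import load_stations
from woodfall.profiles_flux import ConcentrationProfile


@pytest.fixture(scope="session")
def stations():
    return load_stations()


@pytest.fixture
def linear_o2_profile():
    """Exact line 250 -> 0 µM over 0 -> 6.7 mm at ~1 mm resolution."""
    depth = np.linspace(0.0, 6.7, 68)
    value = 250.0 * (1.0 - depth / 6.7)
    return ConcentrationProfile("O2", depth, value, porosity=0.65)


@pytest.fixture
def tiny_tag_table():
    """Four OTUs over three equal-depth samples; no singletons."""
    counts = pd.DataFrame(
        {
            "otu1": [5, 5, 5],   # shared by all
            "otu2": [3, 0, 0],   # unique to s1
            "otu3": [0, 4, 4],   # partial (s2, s3)
            "otu4": [2, 1, 1],   # shared by all
        },
        index=["s1", "s2", "s3"],
    )
    tax = pd.Series(
        {
            "otu1": "Bacteria;Proteobacteria;Gammaproteobacteria;O;F;G1",
            "otu2": "Bacteria;Proteobacteria;Alphaproteobacteria;O;F;G2",
            "otu3": "Bacteria;Firmicutes;Clostridia;O;F;unassigned",
            "otu4": "Bacteria;Actinobacteria;Actinobacteria",
        }
    )
    return TagTable(counts, tax)
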