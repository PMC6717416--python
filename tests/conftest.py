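import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dermrisk import reference
from dermrisk.data_io import ConcentrationTable

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def rfds():
    return reference.rfd_table()


@pytest.fixture(scope="session")
def default_design():
    from dermrisk.synthetic import default_design as _dd

    return _dd()


def make_table(values_by_metal: dict[str, list], brand="b1", color="black",
               lods: dict[str, float] | None = None) -> ConcentrationTable:
    """Build a small in-memory concentration table; None entries are censored."""
    rows = []
    for metal, values in values_by_metal.items():
        lod = (lods or {}).get(metal, 0.05)
        for i, v in enumerate(values):
            rows.append({
                "sample_id": f"s{i}", "brand": brand, "country": "X", "color": color,
                "metal": metal,
                "concentration": np.nan if v is None else float(v),
                "below_lod": v is None, "lod": lod, "imputed": False,
            })
    return ConcentrationTable(pd.DataFrame(rows))


@pytest.fixture
def tiny_table():
    return make_table({"Pb": [0.1, 0.2, 0.3, 0.4]})
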