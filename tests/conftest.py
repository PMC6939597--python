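import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from lipidharmony.nomenclature import parse_shorthand
from lipidharmony.quantify import InternalStandardMap
from lipidharmony.tables import MeasurementTable


@pytest.fixture
def small_is_map():
    return InternalStandardMap(
        class_map={"PC": ("IS PC", 100.0), "Cer": ("IS Cer", 100.0)},
        species_overrides={"LPC 18:1": ("IS LPC 18:1-d7", 50.0)},
    )


def make_table(intensities: dict, roles: dict, **meta_overrides) -> MeasurementTable:
    """Build a MeasurementTable from {feature: {injection: value}} and roles."""
    data = pd.DataFrame(intensities).T
    injections = pd.DataFrame(index=list(data.columns))
    injections["sample"] = [meta_overrides.get("sample", {}).get(c, "s") for c in data.columns]
    injections["role"] = [roles[c] for c in data.columns]
    injections["method"] = meta_overrides.get("method", "m1")
    injections["batch"] = 0
    injections["replicate"] = range(1, len(data.columns) + 1)
    injections["dilution_fraction"] = [
        meta_overrides.get("dilution", {}).get(c, np.nan) for c in data.columns
    ]
    return MeasurementTable(data.astype(float), injections)


@pytest.fixture
def species_of():
    return parse_shorthand
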