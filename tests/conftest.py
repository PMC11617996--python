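import pandas as pd
import pytest

from hdlstruct.proteins import (APOA1_HELIX_REPEATS, ProteinRegistry,
                                load_apoa1, load_apoa2)
from hdlstruct.quantify import QuantTable


@pytest.fixture(scope="session")
def apoa1():
    return load_apoa1()


@pytest.fixture(scope="session")
def apoa2():
    return load_apoa2()


@pytest.fixture(scope="session")
def registry(apoa1, apoa2):
    return ProteinRegistry([apoa1, apoa2])


@pytest.fixture(scope="session")
def helix_annotation():
    return APOA1_HELIX_REPEATS


def make_quant_table(values: dict, groups: dict, space: str = "log2"
                     ) -> QuantTable:
    """Small QuantTable from {feature: row} and {sample: group} dicts."""
    design = pd.DataFrame(
        {"sample_id": list(groups), "group": list(groups.values()),
         "dose": 0.0}
    ).set_index("sample_id")
    frame = pd.DataFrame.from_dict(values, orient="index",
                                   columns=list(groups))
    return QuantTable(values=frame, design=design, space=space)
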