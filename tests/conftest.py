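import numpy as np
import pandas as pd
import pytest

from asorescue.io_formats import AbundanceTable, SampleDesign


@pytest.fixture
def four_arm_design() -> SampleDesign:
    rows = []
    for code, (g, t) in (("PS", ("proband", "ASO_S")), ("PT", ("proband", "ASO_T")),
                         ("CS", ("control", "ASO_S")), ("CT", ("control", "ASO_T"))):
        for r in (1, 2):
            rows.append(dict(sample=f"{code}{r}", genotype=g, treatment=t,
                             replicate=r))
    return SampleDesign(pd.DataFrame(rows).set_index("sample"))


@pytest.fixture
def small_table(four_arm_design) -> AbundanceTable:
    rng = np.random.default_rng(11)
    values = pd.DataFrame(
        rng.normal(20, 1, size=(3, 8)),
        index=["F1", "F2", "F3"],
        columns=four_arm_design.sample_ids,
    )
    return AbundanceTable(values)
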