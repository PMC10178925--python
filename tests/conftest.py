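import numpy as np
import pandas as pd
import pytest

from fringescope.data_model import (
    ASVTable,
    Dataset,
    GeochemTable,
    SampleMetadata,
    TaxonomyTable,
)
from fringescope.synthetic import simulate_study


@pytest.fixture()
def toy_dataset() -> Dataset:
    """3 samples × 5 ASVs, hand-constructed, all invariants satisfied."""
    samples = ["S1", "S2", "S3"]
    geochem = GeochemTable(
        pd.DataFrame(
            {
                "temperature": [85.0, 60.0, 40.0],
                "pH": [7.0, 7.5, 8.0],
                "DO": [0.5, 2.0, 5.0],
                "sulfide": [200.0, 50.0, 5.0],
            },
            index=samples,
        ),
        {"temperature": "degC", "pH": "", "DO": "ppm", "sulfide": "ppb"},
    )
    counts = ASVTable(
        pd.DataFrame(
            np.array([
                [10, 0, 0],
                [5, 5, 0],
                [0, 10, 4],
                [0, 3, 12],
                [1, 2, 4],
            ]),
            index=[f"A{i}" for i in range(1, 6)],
            columns=samples,
        )
    )
    taxonomy = TaxonomyTable.from_lineage_strings({
        "A1": "d__Bacteria;p__Aquificota;c__Aquificae;o__;f__;g__;s__",
        "A2": "d__Bacteria;p__Deinococcota;c__Deinococci;o__;f__;g__;s__",
        "A3": "d__Bacteria;p__Cyanobacteria;c__Cyanobacteriia;o__;f__;g__;s__",
        "A4": "d__Bacteria;p__Chloroflexota;c__Chloroflexia;o__;f__;g__;s__",
        "A5": "d__Bacteria;p__;c__;o__;f__;g__;s__",
    })
    metadata = SampleMetadata(pd.DataFrame({
        "spring_id": ["BP", "BP", "BP"],
        "outflow_index": [1, 2, 3],
        "distance": [0.0, 5.0, 12.0],
        "fringe_label": ["above", "at", "below"],
    }, index=samples))
    return Dataset(geochem, counts, taxonomy, metadata)


@pytest.fixture(scope="session")
def study():
    """Default synthetic study, seed 7 (48 samples, 60 taxa)."""
    return simulate_study(seed=7)
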