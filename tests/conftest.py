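import numpy as np
import pandas as pd
import pytest

from rpfam import (
    CountMatrix,
    PlantedFamily,
    SampleMetadata,
    ScenarioSpec,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_panel():
    """A small simulated panel shared by read-only tests."""
    spec = ScenarioSpec(
        n_families=24,
        n_groups=24,
        n_replicates=2,
        library_size=1_000_000,
        seed=11,
        n_background=40,
        planted={
            0: PlantedFamily("substoichiometric", ratio=0.3),
            1: PlantedFamily("superfluous", ratio=2.5),
            2: PlantedFamily("contrasting"),
            3: PlantedFamily("concerted"),
            4: PlantedFamily("tissue_specific"),
        },
    )
    return generate_dataset(spec)


@pytest.fixture
def toy_counts():
    """Two genes x two libraries with explicit totals (RPKM hand cases)."""
    values = pd.DataFrame(
        {"L1.r1": [100, 0], "L1.r2": [50, 50]},
        index=pd.Index(["g1", "g2"], name="gene_id"),
    )
    totals = pd.Series({"L1.r1": 1e6, "L1.r2": 2e6})
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "library_id": ["L1.r1", "L1.r2"],
                "sample_code": ["L1", "L1"],
                "replicate": [1, 2],
                "series": ["other", "other"],
            }
        )
    )
    return CountMatrix(values=values, library_totals=totals), meta
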