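import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from droughtnet.core_io import AnnotationMap, CountTable

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_table() -> CountTable:
    """Three-gene count table with easy round numbers."""
    counts = pd.DataFrame(
        {
            "R": [100, 10, 0],
            "RT": [100, 80, 0],
            "S": [50, 10, 5],
            "ST": [50, 10, 5],
        },
        index=pd.Index(["BnaA01g00010D", "BnaA01g00020D", "BnaC05g00030D"], name="gene_id"),
    )
    return CountTable(
        counts=counts,
        gene_length_bases=pd.Series([1000, 2000, 500], index=counts.index),
        library_total={"R": 10**6, "RT": 10**6, "S": 10**6, "ST": 10**6},
    )


@pytest.fixture
def toy_annotations() -> AnnotationMap:
    return AnnotationMap(
        gene_to_pathways={
            "g1": {"ko01100", "ko01110"},
            "g2": {"ko01100"},
            "g3": {"ko00500"},
        },
        gene_to_processes={
            "g1": {"GO:0006950"},
            "g2": {"GO:0006950", "GO:0009414"},
        },
        background_gene_count=1000,
    )


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
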