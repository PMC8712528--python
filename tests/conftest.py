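import numpy as np
import pandas as pd
import pytest

from isoswitch.apa_slr import ProbePartition
from isoswitch.io_formats import IntensityMatrix


@pytest.fixture
def simple_partition() -> ProbePartition:
    return ProbePartition(
        probeset_id="ps1", gene_id="G1", split_site=100,
        proximal_probe_ids=["p1", "p2"], distal_probe_ids=["d1", "d2"],
    )


@pytest.fixture
def random_intensity_matrix():
    """6-probe x 8-sample positive matrix with two groups."""
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.lognormal(6, 0.5, size=(6, 8)),
        index=["p1", "p2", "p3", "d1", "d2", "d3"],
        columns=[f"s{i}" for i in range(8)],
    )
    groups = pd.Series(["normal"] * 4 + ["tumor"] * 4, index=values.columns)
    return IntensityMatrix(values=values, sample_groups=groups)
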