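import numpy as np
import pandas as pd
import pytest

from meiorec.genome import GenomeLayout, make_genome_layout
from meiorec.genotypes import LABEL_CALLS, TetradGenotypes


@pytest.fixture(scope="session")
def small_layout():
    """Four-chromosome scaled genome with ~1-kb markers/probes."""
    return make_genome_layout(
        lengths=[300_000, 500_000, 700_000, 900_000],
        centromeres=[100_000, 200_000, 350_000, 400_000],
        marker_spacing=1000,
        probe_spacing=1000,
        jitter=0.2,
        seed=11,
    )


@pytest.fixture(scope="session")
def yeast_layout():
    """Default 16-chromosome yeast-scale layout."""
    return make_genome_layout(seed=5)


def tetrad_from_strings(spores, chrom="chrA", spacing=1000, tetrad_id="t1"):
    """Build a one-chromosome tetrad from four call strings.

    Characters: '1' = P1, '2' = P2, 'N' = missing; marker i sits at
    (i+1)*spacing.
    """
    n = len(spores[0])
    assert len(spores) == 4 and all(len(s) == n for s in spores)
    markers = pd.DataFrame(
        {
            "marker_id": [f"{chrom}_m{i + 1}" for i in range(n)],
            "chrom": chrom,
            "pos": [(i + 1) * spacing for i in range(n)],
        }
    )
    conv = {"1": 0, "2": 1, "N": -1}
    calls = np.array(
        [[conv[spores[j][i]] for j in range(4)] for i in range(n)], dtype=np.int8
    )
    return TetradGenotypes(tetrad_id, markers, calls)


@pytest.fixture
def fig_tetrad():
    return tetrad_from_strings
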