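import numpy as np
import pandas as pd
import pytest

import guidescreen as gs
from guidescreen.screen_data import CountMatrix


def make_count_matrix(
    counts: dict[str, list[int]],
    genes: dict[str, str],
    samples: list[str],
) -> CountMatrix:
    """Tiny CountMatrix from dict-of-rows; control classes from gene labels."""
    from guidescreen.screen_data import _class_from_gene

    ids = list(counts)
    return CountMatrix(
        guide_ids=ids,
        gene_of=dict(genes),
        control_class_of={g: _class_from_gene(genes[g]) for g in ids},
        samples=list(samples),
        counts=pd.DataFrame(
            np.array([counts[g] for g in ids]), index=ids, columns=samples
        ),
    )


@pytest.fixture(scope="session")
def default_collection():
    """One screen under the default study conditions (1000 genes, 12% essential,
    4 guides/gene, 2 replicates)."""
    cfg = gs.SimulationConfig(seed=101)
    screens, truth = gs.simulate_screen_collection(cfg)
    return screens, truth


@pytest.fixture(scope="session")
def small_collection():
    """Fast multi-screen collection for selection tests."""
    cfg = gs.SimulationConfig(
        n_genes=120,
        guides_per_gene=8,
        n_screens=3,
        n_replicates=2,
        seed=202,
    )
    screens, truth = gs.simulate_screen_collection(cfg)
    return screens, truth
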