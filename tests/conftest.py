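import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from evmirna.simulate import DesignSpec, EffectSpec, simulate_counts


@pytest.fixture(scope="session")
def small_sim():
    """A compact full-design simulation shared by read-only tests."""
    design = DesignSpec(n_mirnas=250)
    effects = EffectSpec(
        n_increasing=10, n_decreasing=10, n_genotype_cluster=25, n_ubiquitous=5
    )
    cm, truth = simulate_counts(design, effects, seed=123)
    return cm, truth
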