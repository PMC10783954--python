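import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mipath import SynthSpec, generate


@pytest.fixture(scope="session")
def planted_small():
    """400-sample planted dataset with 10 decoys, strong signal."""
    spec = SynthSpec(n_samples=400, effect_size=2.0, n_decoy_pathways=10, seed=11)
    return generate(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
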