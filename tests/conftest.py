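import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ribopath.simulate import (
    CountSimSpec,
    RTTSSimSpec,
    gen_count_matrix,
    gen_rtts_reads,
)
from ribopath.simulate.counts import standard_design


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_rtts_spec():
    return RTTSSimSpec(
        reference_length=1869,
        planted_sites=[(850, 60.0), (802, 40.0), (700, 20.0)],
        background_rate=0.0,
        n_reads=1200,
        seed=7,
    )


@pytest.fixture
def null_experiment():
    """Small null polysome experiment (no planted TE shifts)."""
    spec = CountSimSpec(
        n_genes=300,
        design=standard_design(n_replicates=3),
        true_size_factors=[1.0, 1.2, 0.8, 1.1, 0.9, 1.0, 1.05, 0.95, 1.0, 1.0, 1.1, 0.9],
        spike_in_count=40,
        dispersion=0.05,
        seed=11,
    )
    return gen_count_matrix(spec)


def random_seq(rng, length, alphabet="ACGT", g_weight=None):
    letters = list(alphabet)
    p = None
    if g_weight is not None:
        p = np.full(len(letters), (1 - g_weight) / (len(letters) - 1))
        p[letters.index("G")] = g_weight
    return "".join(rng.choice(letters, size=length, p=p))
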