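import numpy as np
import pytest

from imgtx import synthetic as syn
from imgtx.expression import ProbeMatrix, build_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_truth():
    return syn.make_truth(n_genes=60, n_signal=6, signal_rho=0.8, seed=11)


@pytest.fixture(scope="session")
def small_bundle(small_truth):
    coords = syn.gen_sample_coords(80, seed=12)
    return syn.gen_expression(60, coords, 3, small_truth, seed=13)


@pytest.fixture(scope="session")
def small_dataset(small_bundle):
    pm = ProbeMatrix(
        small_bundle.probes,
        small_bundle.probe2gene,
        small_bundle.pacall,
        small_bundle.samples,
    )
    return build_dataset(pm, small_bundle.rnaseq)
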