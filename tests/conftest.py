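import numpy as np
import pytest

import hicscape as hs


@pytest.fixture(scope="session")
def small_bins():
    return hs.GenomeBins({"chr1": 500_000, "chr2": 300_000}, 50_000)


@pytest.fixture(scope="session")
def checkerboard_oe():
    """Noiseless checkerboard O/E (infinite-depth limit) plus its spec."""
    spec = hs.make_checkerboard_spec(n_bins=400, contrast=0.6, depth=1e6)
    cmap = hs.expected_rate_map(spec)
    oe = hs.observed_over_expected(hs.kr_balance(cmap))
    return spec, oe


@pytest.fixture(scope="session")
def tad_map_balanced():
    """Poisson-sampled TAD fixture at depth 1e6, balanced."""
    spec = hs.make_tad_spec(depth=1e6)
    cmap = hs.simulate_contact_map(spec, seed=11)
    return spec, hs.kr_balance(cmap)


@pytest.fixture(scope="session")
def loop_map_balanced():
    spec = hs.make_loop_spec(seed=0)
    cmap = hs.simulate_contact_map(spec, seed=21)
    return spec, hs.kr_balance(cmap)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
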