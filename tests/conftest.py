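import numpy as np
import pytest

from mbsv.syndata import (
    CrossConfig,
    build_derived_haplotype,
    mb_toy_reference,
    simulate_cross,
)


@pytest.fixture(scope="session")
def toy_locus():
    """Harmonised toy chromosome + scaled Mb cassette spec and its derived
    haplotype (shared across tests; everything is read-only)."""
    ref, spec = mb_toy_reference(seed=11)
    derived = build_derived_haplotype(ref, spec)
    return ref, spec, derived


@pytest.fixture(scope="session")
def small_cross():
    """A modest fully-penetrant cross used by several mapping tests."""
    bp = list(range(100_000, 5_100_000, 250_000))
    cfg = CrossConfig(
        n_f2=300,
        marker_positions_bp=bp,
        marker_positions_cM=[b / 50_000 for b in bp],
        causal_locus_bp=1_600_000,
        penetrance=1.0,
        seed=42,
    )
    return simulate_cross(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
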