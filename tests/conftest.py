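"""Shared fixtures: small synthetic worlds reused across test modules."""

import pytest

from proteosig.synthetic import SyntheticSpec, make_universe


@pytest.fixture(scope="session")
def small_spec():
    """A scaled-down universe spec for fast structural tests."""
    return SyntheticSpec(
        n_genes=2000, pn_size=250,
        pathway_sizes={"ALP": 80, "UPS": 70, "EXTRACELLULAR": 50,
                       "PROTEOSTASIS_REGULATION": 50},
        group_sizes={"KINASE": 60, "TF": 120, "ION_CHANNEL": 40},
        k=200, expr_genes=400, seed=42)


@pytest.fixture(scope="session")
def small_world(small_spec):
    return make_universe(small_spec)


@pytest.fixture(scope="session")
def default_world7():
    """Full-scale universe at seed 7 (shared; treat as read-only)."""
    spec = SyntheticSpec(seed=7)
    universe, ann, groups = make_universe(spec)
    return spec, universe, ann, groups
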