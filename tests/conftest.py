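import numpy as np
import pytest

from orfscreen.simulate import simulate, simulate_riboseq_scenario


@pytest.fixture(scope="session")
def ribo_scenario():
    """Compact ribo-seq scenario with planted offsets and translated ORFs."""
    annotation, transcripts, profiles, manifest = simulate_riboseq_scenario(
        seed=1, n_coding=30, n_translated=10, n_untranslated=30
    )
    return annotation, transcripts, profiles, manifest


@pytest.fixture(scope="session")
def screen_bundle():
    """Reduced screen-discovery scenario (fast, still funnel-complete)."""
    return simulate(
        seed=1,
        n_coding=15,
        n_lncrna=60,
        n_depleted=12,
        n_confounded=3,
        n_tumor_up=5,
        n_tumor=40,
        n_normal=40,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
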