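import numpy as np
import pytest
from hypothesis import settings

from favamap import linkage, popsim

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def noisy_group():
    """One simulated 150 cM linkage group under realistic noise.

    40 markers, n = 150 individuals, 0.5% genotyping error, 5% missing —
    shared by the ordering tests (session-scoped: the two-point matrices are
    the expensive part).
    """
    tm = popsim.make_true_map(
        n_markers=40, group_lengths_cM=(150.0,), rng_seed=100, distortion_region=False
    )
    cfg = popsim.SimConfig(
        population_size=150, missing_rate=0.05, genotyping_error_rate=0.005, rng_seed=101
    )
    gm, truth = popsim.simulate_f3_population(tm, cfg)
    collapsed, bins = linkage.collapse_cosegregating(gm)
    pairs = linkage.pairwise_linkage(collapsed)
    return {
        "true_group": tm.groups[0],
        "genotypes": collapsed,
        "bins": bins,
        "pairs": pairs,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def clean_group():
    """Error-free, fully observed version of a 120 cM group (30 markers)."""
    tm = popsim.make_true_map(
        n_markers=30, group_lengths_cM=(120.0,), rng_seed=102, distortion_region=False
    )
    cfg = popsim.SimConfig(
        population_size=200, missing_rate=0.0, genotyping_error_rate=0.0, rng_seed=103
    )
    gm, truth = popsim.simulate_f3_population(tm, cfg)
    collapsed, bins = linkage.collapse_cosegregating(gm)
    pairs = linkage.pairwise_linkage(collapsed)
    return {
        "true_group": tm.groups[0],
        "genotypes": collapsed,
        "bins": bins,
        "pairs": pairs,
        "truth": truth,
    }
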