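import numpy as np
import pytest

import sdmtransfer as st
from sdmtransfer.synthetic import ScenarioConfig


@pytest.fixture(scope="session")
def small_landscape():
    """A 60x90 landscape with the default virtual species."""
    cfg = ScenarioConfig(nrows=60, ncols=90, seed_landscape=7,
                         seed_sampling=8, n_presences=200)
    stack, regions, truth = st.generate_landscape(cfg)
    return cfg, stack, regions, truth


@pytest.fixture(scope="session")
def small_design(small_landscape):
    """Presence/background design on the small landscape."""
    cfg, stack, regions, truth = small_landscape
    occ = st.sample_presences(truth, cfg.n_presences, cfg.seed_sampling)
    bg = st.sample_background(stack.template, 1000, 99, regions=regions)
    design = st.build_design(occ, bg, stack)
    return design


@pytest.fixture(scope="session")
def small_fit(small_landscape, small_design):
    """A fast ensemble fit reused by evaluation/ensemble tests."""
    cfg, stack, regions, truth = small_landscape
    occ = st.sample_presences(truth, cfg.n_presences, cfg.seed_sampling)
    bg = st.sample_background(stack.template, 1000, 99, regions=regions)
    fit = st.fit_ensemble(occ, bg, stack,
                          st.FitConfig(gbm_n_trees=40), seed=5)
    return fit, stack, regions, truth
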