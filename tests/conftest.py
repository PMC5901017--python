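import warnings

import numpy as np
import pandas as pd
import pytest

from dziop import (EquationSpec, ParameterSet, build_design, condensed_preset,
                   fit, simulate_dataset)


@pytest.fixture(scope="session")
def tiny_spec():
    return EquationSpec("y", ["x"], ["x"], ["x"])


@pytest.fixture(scope="session")
def tiny_obs(tiny_spec):
    """Twelve deterministic rows covering all four categories."""
    df = pd.DataFrame({"y": [0, 1, 2, 3] * 3, "x": np.linspace(-2, 2, 12)})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_design(df, tiny_spec)


@pytest.fixture(scope="session")
def centered_params():
    """All latent indices zero at x=0: the hand-checkable configuration."""
    return ParameterSet(beta_r=[0.0, 0.0], beta_m=[0.0, 0.0],
                        beta_y=[0.0, 0.0], mu=[0.8, 1.6], variant="DZIOP")


@pytest.fixture(scope="session")
def dziop_sim():
    """Small uncorrelated double-hurdle sample with latent records."""
    cfg = condensed_preset(n=1500, seed=42, correlated=False)
    table, latents = simulate_dataset(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        obs = build_design(table, cfg.spec, "DZIOP")
    return cfg, table, latents, obs


@pytest.fixture(scope="session")
def dziop_fit_small(dziop_sim):
    cfg, table, latents, obs = dziop_sim
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit(obs, "DZIOP", seed=7)
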