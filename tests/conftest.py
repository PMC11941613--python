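import numpy as np
import pytest

from nmjmorph import MorphometryConfig
from nmjmorph.synthetic import NMJParams, RenderConfig, render_nmj_stack


@pytest.fixture(scope="session")
def compact_render():
    return RenderConfig.compact()


@pytest.fixture(scope="session")
def rendered_nmj(compact_render):
    """One noisy rendered NMJ shared across tests (seed fixed)."""
    params = NMJParams(
        target_endplate_volume=1800.0,
        target_pre_volume=1350.0,
        target_apposition=0.66,
        branch_count=5,
        seed=7,
    )
    stack, truth = render_nmj_stack(params, compact_render)
    return params, stack, truth


@pytest.fixture(scope="session")
def noiseless_nmj():
    """Blur-free, noise-free render: thresholding is exact."""
    params = NMJParams(
        target_endplate_volume=1800.0,
        target_pre_volume=1350.0,
        target_apposition=0.66,
        branch_count=5,
        seed=11,
        noise_level=0.0,
    )
    render = RenderConfig.compact(sigma_lateral=0.0, sigma_axial=0.0)
    stack, truth = render_nmj_stack(params, render)
    return params, stack, truth
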