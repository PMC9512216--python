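import numpy as np
import pytest

from plumetrack import ExpansionParams, PlumeScenario, generate_plume_scenario


@pytest.fixture(scope="session")
def small_scenario() -> PlumeScenario:
    """Short noise-free scenario with motion in every direction."""
    return PlumeScenario(
        expansion_params={
            "x_front": ExpansionParams(A=0.8, tau=1.5, drift=0.01),
            "y_half": ExpansionParams(A=0.4, tau=2.0, drift=0.005),
            "z_up": ExpansionParams(A=0.5, tau=2.0),
            "z_down": ExpansionParams(A=0.3, tau=2.5),
        },
        task_duration_s=4.0,
        post_task_s=4.0,
        fps=10.0,
        frame_size_px=(160, 240),
        side_origin_px=(80, 30),
        top_origin_px=(80, 30),
        metres_per_pixel=0.01,
        noise_sd=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_render(small_scenario):
    return generate_plume_scenario(small_scenario)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
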