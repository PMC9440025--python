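import numpy as np
import pytest

from oholidar import LidarGeometry, fit_msc_model, generate_scene
from oholidar.iop_model import PhaseFunction, make_profile


@pytest.fixture(scope="session")
def geom40():
    """Fixed-station geometry: 40 degree incidence, 200 mrad FOV."""
    return LidarGeometry(H=5.0, theta_i_deg=40.0, fov=0.2, n=1.34)


@pytest.fixture(scope="session")
def geom60():
    """Underway geometry: 60 degree incidence."""
    return LidarGeometry(H=5.0, theta_i_deg=60.0, fov=0.2, n=1.34)


@pytest.fixture(scope="session")
def prof_hom():
    """Homogeneous moderately turbid column: a=0.08, b=0.2, b_b=0.004 per m."""
    return make_profile(
        [(0.0, 25.0, 0.08, 0.2, 0.004)],
        phase_fn=PhaseFunction(backscatter_fraction=0.02),
    )


@pytest.fixture(scope="session")
def msc_model40(geom40):
    """MSC model trained on the default 5x5 (a, b_b) grid at 40 degrees."""
    return fit_msc_model(geom=geom40)


@pytest.fixture(scope="session")
def scene_suite(geom40):
    """Default noiseless scene suite: two homogeneous columns and a layered one."""
    geo = {"H": 5.0, "theta_i_deg": 40.0, "fov": 0.2, "n": 1.34}
    return [
        generate_scene({"template": "homogeneous", "n_columns": 2, "a": 0.08,
                        "b_b": 0.004, "geometry": geo}, seed=11),
        generate_scene({"template": "homogeneous", "n_columns": 2, "a": 0.15,
                        "b_b": 0.007, "geometry": geo}, seed=12),
        generate_scene({"template": "gaussian_layer", "n_columns": 2, "a": 0.1,
                        "b_b": 0.003, "layers": [(10.0, 1.5, 0.003)],
                        "geometry": geo}, seed=13),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
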