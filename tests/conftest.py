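import numpy as np
import pytest

from lvmotion.mesh import build_uniform_mesh
from lvmotion.phantom import PhantomSpec, default_geometry, render_frame
from lvmotion.preprocess import binarize_tags, estimate_geometry, normalize_intensity

# the worked-example normalized deformation used across the suite
EXAMPLE_ALPHA_NORM = 0.31
EXAMPLE_BETA_NORM = -0.14


@pytest.fixture(scope="session")
def true_geometry():
    return default_geometry()


@pytest.fixture(scope="session")
def example_frames():
    """Noise-free, non-fading phantom pair: end-diastolic frame and the
    worked-example deformed frame, with ground-truth masks."""
    spec = PhantomSpec(
        n_frames=2,
        alpha_profile=[0.0, EXAMPLE_ALPHA_NORM],
        beta_profile=[0.0, EXAMPLE_BETA_NORM],
        fading=[1.0, 1.0],
    )
    f0, m0 = render_frame(spec, 0)
    f1, m1 = render_frame(spec, 1)
    return {"spec": spec, "frame0": f0, "mask0": m0, "frame1": f1, "mask1": m1}


@pytest.fixture(scope="session")
def estimated_geometry(example_frames):
    return estimate_geometry(example_frames["frame0"], pixel_spacing=(1.0, 1.0))


@pytest.fixture(scope="session")
def example_binary(example_frames, estimated_geometry):
    """Binarized worked-example frame (the fitter's input)."""
    norm = normalize_intensity(example_frames["frame1"])
    return binarize_tags(norm, estimated_geometry)


@pytest.fixture(scope="session")
def base_mesh(estimated_geometry):
    return build_uniform_mesh(estimated_geometry, 7.0, 1.5, sample_step=0.4)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
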