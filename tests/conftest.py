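import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def aligned_phantom_spec():
    """Equal PET/CT grids with an integer-translation misalignment: the
    only regime where resampling is exact, so end-to-end mask recovery
    can be checked for strict equality."""
    from petct_label import AffineParams, BodyEllipse, Lesion, PhantomSpec

    return PhantomSpec(
        ct_size=(128, 128),
        pet_size=(128, 128),
        lesions=[Lesion(64, 70, 5, 20)],
        body_ellipse=BodyEllipse(64, 64, 50, 45),
        misalign=AffineParams(1, 0, 0, 1, 4, -3),
        noise_sigma=0.0,
        rng_seed=1,
    )
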