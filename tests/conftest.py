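import numpy as np
import pytest
from hypothesis import settings

from batquant import EmissionImage

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20190515)


def make_image(voxels, spacing=(1.0, 1.0, 1.0), unit="Bq_per_cc",
               modality="PET", dose=5e7, weight=500.0, isotope="F18",
               schedule=()):
    return EmissionImage(
        voxels=voxels, spacing_mm=spacing, value_unit=unit,
        modality=modality, injected_dose_Bq=dose, body_weight_g=weight,
        isotope=isotope, frame_schedule=schedule,
    )


@pytest.fixture
def image_factory():
    return make_image
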