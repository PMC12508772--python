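import numpy as np
import pytest

from t1map.synthkspace import (AcquisitionSpec, SamplingMask,
                               make_sphere_phantom, make_synthetic_coil_maps,
                               make_sampling_mask, simulate_image_series)


@pytest.fixture(scope="session")
def small_spec() -> AcquisitionSpec:
    """Desk-scale protocol: default TI schedule / TR on a 24x24x16 grid."""
    return AcquisitionSpec(matrix_dims=(24, 24, 16), n_coils=4,
                           undersampling_factor=1.0)


@pytest.fixture(scope="session")
def two_sphere_phantom(small_spec):
    """Two spheres with the white-matter- and cortex-mimic T1 values."""
    ph = make_sphere_phantom(
        small_spec.matrix_dims,
        [((8.0, 12.0, 8.0), 5.0, 252.8, 1.0, None),
         ((16.0, 12.0, 8.0), 5.0, 354.4, 0.9, None)])
    x, y, z = (np.linspace(-1, 1, d) for d in small_spec.matrix_dims)
    xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")
    ph.background_phase = 0.5 * xx + 0.3 * yy - 0.4 * zz
    return ph


@pytest.fixture(scope="session")
def small_images(two_sphere_phantom, small_spec):
    return simulate_image_series(two_sphere_phantom, small_spec)


@pytest.fixture(scope="session")
def small_maps(small_spec):
    return make_synthetic_coil_maps(small_spec.n_coils,
                                    small_spec.matrix_dims, seed=0)


@pytest.fixture(scope="session")
def shutter_mask(small_spec):
    return make_sampling_mask(small_spec, seed=1)


@pytest.fixture(scope="session")
def full_mask(small_spec):
    """All-ones mask (no shutter): the exact-round-trip sampling pattern."""
    _, ny, nz = small_spec.matrix_dims
    return SamplingMask(mask=np.ones((small_spec.n_ti, ny, nz), np.uint8),
                        shutter=np.ones((ny, nz), bool), seed=0)
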