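import dataclasses

import numpy as np
import pytest

from dtialps import DWIVolume, PhantomSpec, fit_tensor, make_phantom
from dtialps.gradients import default_gradient_table


@pytest.fixture(scope="session")
def gtab():
    return default_gradient_table(seed=0)


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def noiseless_phantom(default_spec, gtab):
    return make_phantom(default_spec, gtab)


@pytest.fixture(scope="session")
def noiseless_dwi(noiseless_phantom):
    return DWIVolume(data=noiseless_phantom.dwi, affine=noiseless_phantom.affine)


@pytest.fixture(scope="session")
def fitted_field(noiseless_dwi, gtab):
    return fit_tensor(noiseless_dwi, gtab, method="ols")


@pytest.fixture(scope="session")
def slice_mask(default_spec):
    """Restrict fits to the ventricle-body slice (where both ROIs live)."""
    m = np.zeros(default_spec.grid_shape, dtype=bool)
    m[:, :, default_spec.ventricle_body_slice] = True
    return m


def spec_with(spec, **kwargs):
    return dataclasses.replace(spec, **kwargs)
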