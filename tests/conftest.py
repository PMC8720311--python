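import numpy as np
import pytest

from polsdom import (
    DipoleField,
    ModulationScheme,
    PSFModel,
    render_stack,
)


@pytest.fixture
def scheme4x30() -> ModulationScheme:
    return ModulationScheme(4, 30)


@pytest.fixture
def delta_psf() -> PSFModel:
    return PSFModel.delta(pixel_size_nm=20.0)


@pytest.fixture
def gaussian_psf() -> PSFModel:
    return PSFModel(kind="gaussian", fwhm_nm=200.0, pixel_size_nm=20.0)


def single_emitter_field(
    shape=(16, 16), gdc=1.0, gac=1.0, alpha_deg=30.0, pixel_size_nm=20.0
) -> DipoleField:
    f = DipoleField.empty(shape, pixel_size_nm)
    cy, cx = shape[0] // 2, shape[1] // 2
    f.gdc[cy, cx] = gdc
    f.gac[cy, cx] = gac
    f.alpha_deg[cy, cx] = alpha_deg
    return f


@pytest.fixture
def single_emitter_stack(scheme4x30, delta_psf):
    """Noiseless delta-PSF stack of one gdc=1, gac=1, alpha=30 deg emitter."""
    field = single_emitter_field()
    return render_stack(field, delta_psf, scheme4x30), field


def cosine_fit_oracle(trace: np.ndarray, theta_rad: np.ndarray):
    """Independent least-squares oracle for (A, B, alpha_deg) of a trace."""
    X = np.column_stack([np.ones_like(theta_rad), np.cos(2 * theta_rad), np.sin(2 * theta_rad)])
    (a0, a1, a2), *_ = np.linalg.lstsq(X, trace, rcond=None)
    B = float(np.hypot(a1, a2))
    alpha = float(np.mod(np.rad2deg(np.arctan2(a2, a1)) / 2.0, 180.0))
    return float(a0), B, alpha
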