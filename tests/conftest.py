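import dataclasses

import numpy as np
import pytest

import dcevasc as dv


@pytest.fixture(scope="session")
def frame_times():
    """13 s grid covering 0..364 s, five pre-injection frames."""
    return np.arange(0, 365, 13.0)


@pytest.fixture(scope="session")
def default_aif(frame_times):
    return dv.generate_aif(dv.AIFParams(), frame_times)


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Heterogeneous noiseless phantom with a coil bias field."""
    spec = dv.PhantomSpec(grid_shape=(16, 16, 6), tumor_axes=(5.0, 5.0, 3.0),
                          heterogeneity=0.3, bias_field_strength=0.3,
                          noise_sigma=0.0, seed=11)
    return dv.generate_phantom(spec)


@pytest.fixture(scope="session")
def homogeneous_phantom():
    """Noiseless phantom at the clinical baseline medians, no spatial
    heterogeneity: Ktrans=0.13/min, kep=0.55/min, vp=0.094."""
    spec = dv.PhantomSpec(grid_shape=(14, 14, 6), tumor_axes=(4.0, 4.0, 2.5),
                          heterogeneity=0.0, bias_field_strength=0.3,
                          noise_sigma=0.0, seed=3)
    return dv.generate_phantom(spec)


@pytest.fixture(scope="session")
def recovered_concentration(noiseless_phantom):
    """Full preprocessing path applied to the noiseless phantom."""
    ph = noiseless_phantom
    corrected = dv.b1_correct(ph.dce, ph.breast_coil, ph.body_coil)
    t10 = np.where(ph.lv_mask.data, 1200.0, 900.0)
    return dv.signal_to_concentration(corrected, ph.spec.conversion, t10,
                                      n_pre_frames=ph.spec.n_pre_frames)


def snr20_spec():
    spec = dv.PhantomSpec(grid_shape=(24, 24, 10), tumor_axes=(8.0, 7.0, 6.0),
                          heterogeneity=0.0, bias_field_strength=0.3, seed=5)
    return dataclasses.replace(spec, noise_sigma=dv.sigma_for_snr(spec, 20))
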