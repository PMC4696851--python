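"""Shared fixtures: synthetic two-stain samples and fitted models."""

import numpy as np
import pytest

from bistain import deconvolve, fit_stain_model, generate_ihc


@pytest.fixture(scope="session")
def hdab_sample():
    """Default-condition synthetic H-DAB image (OD noise SD 0.02, 5 deg
    stain-vector perturbation)."""
    return generate_ihc(seed=7)


@pytest.fixture(scope="session")
def quiet_sample():
    """Low-noise synthetic image (OD noise SD 0.01) for recovery checks
    whose tolerances are set by binning/quantization, not sensor noise."""
    return generate_ihc(seed=7, noise_sd=0.01)


@pytest.fixture(scope="session")
def clean_sample():
    """Noise-free synthetic image: errors are 8-bit quantization only."""
    return generate_ihc(seed=7, noise_sd=0.0)


@pytest.fixture(scope="session")
def fitted_model(hdab_sample):
    return fit_stain_model(hdab_sample.image)


@pytest.fixture(scope="session")
def concentrations(hdab_sample, fitted_model):
    conc = deconvolve(hdab_sample.image, fitted_model.basis)
    conc.normalize()
    return conc


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
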