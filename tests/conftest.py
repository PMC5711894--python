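"""Shared fixtures: small rendered scenes and the default calibration."""

import pytest

from granuvisc.decay_fit import fit_image
from granuvisc.flim_synth import OpticalConfig, make_phantom, render_tcspc
from granuvisc.rotor_calibration import default_calibration


@pytest.fixture(scope="session")
def curve():
    return default_calibration()


@pytest.fixture(scope="session")
def small_scene():
    """10 granules in a 96x96 frame, rendered at the default photon budget."""
    phantom, truth = make_phantom("nonCF", 10, frame=(96, 96), seed=3)
    img = render_tcspc(phantom, truth, seed=4)
    return phantom, truth, img


@pytest.fixture(scope="session")
def small_lifetime_image(small_scene):
    _, _, img = small_scene
    return fit_image(img)


@pytest.fixture(scope="session")
def optics():
    return OpticalConfig()
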