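import numpy as np
import pytest

from prokmorph import (FieldSpec, bead_field, builtin_cruise_profiles,
                       calibrate_with_beads, render_micrograph)

BEAD_DIAMETER = 2.13  # µm, monosized calibration beads


@pytest.fixture(scope="session")
def profiles():
    return builtin_cruise_profiles()


@pytest.fixture(scope="session")
def nf_field():
    """Default camera geometry with PSF and noise switched off."""
    return FieldSpec().noise_free()


@pytest.fixture(scope="session")
def default_field():
    return FieldSpec()


@pytest.fixture(scope="session")
def nf_calibration(nf_field):
    beads = bead_field(24, BEAD_DIAMETER, nf_field, seed=0)
    img, _ = render_micrograph(beads, nf_field, seed=0)
    return calibrate_with_beads(img, BEAD_DIAMETER, nf_field.pixel_size)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
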