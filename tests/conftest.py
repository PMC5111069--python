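import numpy as np
import pytest

import ribodyn as rd


@pytest.fixture(scope="session")
def catalog():
    return rd.fixture_catalog()


@pytest.fixture(scope="session")
def in16():
    return rd.INSTRUMENTS["IN16"]


@pytest.fixture(scope="session")
def in5():
    return rd.INSTRUMENTS["IN5_5.1A"]


@pytest.fixture(scope="session")
def scan_temperatures():
    return np.arange(250.0, 311.0, 5.0)


@pytest.fixture(scope="session")
def noiseless_qens_fits(catalog, in5):
    """Noiseless QENS simulate->fit round trips, shared by several tests."""
    out = {}
    for name in ("h30s_nacl", "h50s_nacl"):
        model = catalog[name]
        spec = rd.simulate_qens(model, in5, 298.0)
        out[name] = (model, spec, rd.fit_qens(spec, in5.resolution_fwhm))
    return out


def tiny_model(**overrides):
    """Small hand-set sample model for targeted tests."""
    base = dict(
        name="tiny",
        water_fraction=0.6,
        immobile_fraction=0.1,
        p_hyd=0.3,
        p_free=0.6,
        d_free=0.23, tau_free=1.1,
        d_hyd=0.05, tau_hyd=5.0,
        msd_ref=12.0,
        slope_above=0.1,
        slope_below=0.025,
    )
    base.update(overrides)
    return rd.SampleModel(**base)
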