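import pytest

import coilcomb as cc


@pytest.fixture(scope="session")
def model31():
    """Default phosphorus spectral model (256 points, 5 kHz)."""
    return cc.default_model_31p()


@pytest.fixture(scope="session")
def fid31(model31):
    return cc.spectrum_to_fid(cc.make_spectrum(model31), model31.dwell_s)


@pytest.fixture(scope="session")
def small_phantom():
    """A small noiseless CSI phantom plus its true sensitivity maps."""
    grid = (6, 6, 2)
    nch = 4
    cmap, b = cc.default_phantom_maps(grid, nch)
    model = cc.default_model_31p(n_points=64)
    models = {1: model, 2: cc.scale_model(model, 0.4)}
    csi = cc.synth_csi_phantom(cmap, models, b, sigma=0.0)
    return csi, b
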