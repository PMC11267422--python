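import numpy as np
import pytest

from terpord import synth
from terpord.topology import load_topology


@pytest.fixture(scope="session")
def registry():
    return load_topology()


@pytest.fixture(scope="session")
def small_bilayer_frames():
    """A small mixed D9PC/DPOP bilayer: 16 lipids per leaflet, 5 frames."""
    model = synth.ToyBilayerModel(
        n_lipids_per_leaflet=16, sterol="DPOP", sterol_fraction=0.25, seed=7
    )
    return model, synth.gen_bilayer(model, n_frames=5)


@pytest.fixture(scope="session")
def noiseless_models():
    return synth.reference_isotherm_models(noise_sd=0.0, n_replicates=1, seed=0)


def gaussian_histogram(mean, sd, width=0.87, lo=-40.0, hi=40.0, label=""):
    """Histogram1D carrying exact Gaussian bin masses (analytic, not sampled)."""
    from scipy.stats import norm

    from terpord.trajectory import ZHistogram

    nbins = int(np.ceil((hi - lo) / width))
    edges = lo + np.arange(nbins + 1) * width
    mass = norm.cdf(edges[1:], mean, sd) - norm.cdf(edges[:-1], mean, sd)
    mass = mass / mass.sum()
    return ZHistogram(edges=edges, densities=mass / width, label=label)
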