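import numpy as np
import pytest

from groupbrdf import brdf
from groupbrdf.synth import SyntheticSceneSpec, generate_group

# Static six-bin stratification with the discrete NDVI levels placed at the
# bin centers, so per-bin constant coefficients are exactly true.
SIX_BIN_EDGES = np.linspace(0.05, 1.0, 7)
SIX_BIN_LEVELS = 0.5 * (SIX_BIN_EDGES[:-1] + SIX_BIN_EDGES[1:])


@pytest.fixture(scope="session")
def exact_scene():
    """Noiseless, flat-terrain, discrete-NDVI 3-line group: the forward
    model is exactly invertible by the pipeline."""
    spec = SyntheticSceneSpec(
        n_lines=3, n_rows=120, n_cols=80, ndvi_field="discrete",
        ndvi_levels=SIX_BIN_LEVELS.copy(), terrain="flat",
        noise_sigma=0.0, seed=11,
    )
    lines, truth = generate_group(spec)
    return spec, lines, truth


@pytest.fixture(scope="session")
def six_bins():
    return brdf.NdviBinSpec(mode="static", n_bins=6, lower_mask=0.05,
                            edges=SIX_BIN_EDGES.copy())


@pytest.fixture(scope="session")
def exact_group(exact_scene):
    """(cube, obs, ndvi) triples of the exact scene."""
    _, lines, _ = exact_scene
    return [(cube, obs, brdf.compute_ndvi(cube)) for cube, obs in lines]


@pytest.fixture(scope="session")
def exact_table(exact_scene, exact_group, six_bins):
    """Group fit of the exact scene, reference zenith = pooled mean."""
    _, _, truth = exact_scene
    samples = brdf.stratified_group_sample(exact_group, six_bins,
                                           per_bin=800, seed=5)
    return brdf.fit_brdf_coefficients(
        samples, six_bins, smoothing="none",
        reference_zenith=truth.pooled_solar_zenith_mean)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
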