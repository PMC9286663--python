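import numpy as np
import pytest

from groupbrdf import brdf, envi
from groupbrdf.errors import ConfigurationError, DataError
from groupbrdf.kernels import KernelChoice, kernels_at
from groupbrdf.synth import SyntheticSceneSpec, generate_group, truth_report

from _oracles import li_scalar, ross_scalar


# ---------------------------------------------------------------------------
# NDVI


def _two_band_cube(red, nir):
    red = np.atleast_2d(np.asarray(red, float))
    nir = np.atleast_2d(np.asarray(nir, float))
    header = envi.SceneHeader(n_rows=red.shape[0], n_cols=red.shape[1], n_bands=2,
                              wavelengths=np.array([665.0, 850.0]))
    return envi.ReflectanceCube(header, np.stack([red, nir]),
                                np.ones(red.shape, bool))


@pytest.mark.parametrize(
    "red, nir, expected",
    [(0.3, 0.3, 0.0), (0.0, 0.4, 1.0), (0.05, 0.45, 0.8)],
)
def test_compute_ndvi_values(red, nir, expected):
    nd = brdf.compute_ndvi(_two_band_cube([[red]], [[nir]]))
    assert nd[0, 0] == pytest.approx(expected, abs=1e-14)


def test_compute_ndvi_nonpositive_sum_masked():
    nd = brdf.compute_ndvi(_two_band_cube([[0.0]], [[0.0]]))
    assert np.isnan(nd[0, 0])


def test_compute_ndvi_requires_bands_near_targets():
    header = envi.SceneHeader(n_rows=1, n_cols=1, n_bands=2,
                              wavelengths=np.array([500.0, 600.0]))
    cube = envi.ReflectanceCube(header, np.full((2, 1, 1), 0.2), np.ones((1, 1), bool))
    with pytest.raises(ConfigurationError):
        brdf.compute_ndvi(cube)


def test_nearest_band_threshold():
    wl = np.arange(400.0, 2501.0, 10.0)
    assert wl[brdf.nearest_band(wl, 850.0)] == 850.0
    with pytest.raises(ConfigurationError):
        brdf.nearest_band(wl, 851.0, tol_nm=0.5)
    with pytest.raises(ConfigurationError):
        brdf.nearest_band(np.array([400.0]), 420.1, tol_nm=20.0)


# ---------------------------------------------------------------------------
# bins


def test_static_bins_equal_width():
    spec = brdf.build_bins(None, brdf.NdviBinSpec(mode="static", n_bins=3))
    np.testing.assert_allclose(np.diff(spec.edges), (1.0 - 0.05) / 3)
    assert spec.edges[0] == 0.05 and spec.edges[-1] == 1.0


def test_dynamic_bins_uniform_sample_near_equal_width(rng):
    vals = rng.uniform(0.05, 0.9, 200_000)
    spec = brdf.build_bins(vals, brdf.NdviBinSpec(mode="dynamic", n_bins=18))
    inner = spec.edges[1:-1]
    expected = np.linspace(0.05, 0.9, 19)[1:-1]
    np.testing.assert_allclose(inner, expected, atol=0.01)
    assert spec.edges[-1] == 1.0


def test_dynamic_bins_sort_and_split_oracle():
    vals = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8])
    spec = brdf.build_bins(vals, brdf.NdviBinSpec(mode="dynamic", n_bins=4))
    # oracle: explicit quantiles of the sorted vector (linear interpolation)
    expected_inner = np.quantile(vals, [0.25, 0.5, 0.75])
    np.testing.assert_allclose(spec.edges[1:-1], expected_inner)
    counts = np.bincount(brdf.assign_bins(vals, spec), minlength=4)
    assert counts.sum() == vals.size and counts.min() >= 1


def test_dynamic_bins_too_few_distinct_values():
    with pytest.raises(DataError, match="3"):
        brdf.build_bins(np.array([0.2, 0.4, 0.6]),
                        brdf.NdviBinSpec(mode="dynamic", n_bins=8))


def test_assign_bins_edges_and_mask():
    spec = brdf.build_bins(None, brdf.NdviBinSpec(mode="static", n_bins=3))
    nd = np.array([0.04, 0.05, 0.3666, 0.7, 1.0, np.nan])
    got = brdf.assign_bins(nd, spec)
    np.testing.assert_array_equal(got, [-1, 0, 0, 2, 2, -1])


# ---------------------------------------------------------------------------
# sampling


def test_sampling_deterministic(exact_group, six_bins):
    s1 = brdf.stratified_group_sample(exact_group, six_bins, per_bin=200, seed=9)
    s2 = brdf.stratified_group_sample(exact_group, six_bins, per_bin=200, seed=9)
    np.testing.assert_array_equal(s1.reflectance, s2.reflectance)
    np.testing.assert_array_equal(s1.bin_id, s2.bin_id)
    np.testing.assert_array_equal(s1.line_id, s2.line_id)


def test_sampling_exhaustion_rule(exact_group, six_bins):
    """per_bin above a bin's population draws every pixel exactly once."""
    huge = brdf.stratified_group_sample(exact_group, six_bins,
                                        per_bin=10**9, seed=0)
    counts = np.bincount(huge.bin_id, minlength=6)
    pop = np.zeros(6, int)
    for cube, obs, nd in exact_group:
        ok = cube.valid_mask & obs.valid_mask & np.isfinite(nd)
        b = brdf.assign_bins(nd, six_bins)
        pop += np.bincount(b[ok & (b >= 0)], minlength=6)
    np.testing.assert_array_equal(counts, pop)


def test_sampling_proportional_to_eligible_area(exact_scene, six_bins):
    """Two lines with a 3:1 eligible-pixel ratio contribute ~3:1 samples."""
    _, lines, _ = exact_scene
    (cube_a, obs_a), (cube_b, obs_b) = lines[0], lines[1]
    cube_b = cube_b.copy()
    keep = np.zeros(cube_b.valid_mask.shape, bool)
    keep[: cube_b.header.n_rows // 3] = True  # keep ~1/3 of line b
    cube_b.valid_mask &= keep
    group = [(cube_a, obs_a, brdf.compute_ndvi(cube_a)),
             (cube_b, obs_b, brdf.compute_ndvi(cube_b))]
    n_a = group[0][0].valid_mask.sum()
    n_b = group[1][0].valid_mask.sum()
    samples = brdf.stratified_group_sample(group, six_bins, per_bin=500, seed=3)
    share_a = (samples.line_id == 0).mean()
    p = n_a / (n_a + n_b)
    se = np.sqrt(p * (1 - p) / samples.n_samples)
    assert abs(share_a - p) < 5 * se


# ---------------------------------------------------------------------------
# fitting


def _geometry_samples(n, seed=0):
    rng = np.random.default_rng(seed)
    return (rng.uniform(np.radians(20), np.radians(55), n),
            rng.uniform(0.0, np.radians(17.5), n),
            rng.uniform(0.0, np.pi, n))


def _one_bin():
    return brdf.NdviBinSpec(mode="static", n_bins=1, lower_mask=0.05,
                            edges=np.array([0.05, 1.0]))


def _sample_set(refl, ts, tv, phi, ndvi=None, bin_id=None):
    n = refl.shape[0]
    return brdf.SampleSet(
        reflectance=refl, theta_s=ts, theta_v=tv, phi=phi,
        ndvi=np.full(n, 0.5) if ndvi is None else ndvi,
        bin_id=np.zeros(n, int) if bin_id is None else bin_id,
        line_id=np.zeros(n, int), seed=0)


def test_fit_constant_reflectance_is_pure_isotropic():
    ts, tv, phi = _geometry_samples(400)
    samples = _sample_set(np.full((400, 2), 0.5), ts, tv, phi)
    table = brdf.fit_brdf_coefficients(samples, _one_bin())
    np.testing.assert_allclose(table.f_iso[0], 0.5, atol=1e-12)
    np.testing.assert_allclose(table.f_geo[0], 0.0, atol=1e-12)
    np.testing.assert_allclose(table.f_vol[0], 0.0, atol=1e-12)


def test_fit_recovers_forward_generated_coefficients():
    ts, tv, phi = _geometry_samples(500, seed=2)
    truth = np.array([[0.3, 0.005, 0.1], [0.22, 0.012, 0.3]])
    kg, kv = kernels_at(ts, tv, phi)
    refl = np.stack([t[0] + t[1] * kg + t[2] * kv for t in truth], axis=1)
    table = brdf.fit_brdf_coefficients(_sample_set(refl, ts, tv, phi), _one_bin())
    np.testing.assert_allclose(table.f_iso[0], truth[:, 0], atol=1e-8)
    np.testing.assert_allclose(table.f_geo[0], truth[:, 1], atol=1e-8)
    np.testing.assert_allclose(table.f_vol[0], truth[:, 2], atol=1e-8)


def test_fit_single_geometry_flagged_rank_deficient():
    n = 50
    ts = np.full(n, np.radians(40.0))
    tv = np.full(n, np.radians(10.0))
    phi = np.full(n, 1.0)
    samples = _sample_set(np.full((n, 2), 0.4), ts, tv, phi)
    with pytest.raises(DataError):
        brdf.fit_brdf_coefficients(samples, _one_bin())


def test_fit_group_recovery_matches_generator(exact_scene, exact_group, six_bins):
    _, _, truth = exact_scene
    samples = brdf.stratified_group_sample(exact_group, six_bins, per_bin=800, seed=5)
    table = brdf.fit_brdf_coefficients(samples, six_bins, smoothing="none")
    rep = truth_report(truth, table)
    assert rep["max_abs_error"] < 1e-8


def test_truth_report_self_comparison_zero(exact_scene, exact_table):
    _, _, truth = exact_scene
    t_iso, t_geo, t_vol = truth.coefficients_at(exact_table.bin_centers)
    from dataclasses import replace

    self_table = replace(exact_table, f_iso=t_iso, f_geo=t_geo, f_vol=t_vol)
    rep = truth_report(truth, self_table)
    assert rep["max_abs_error"] == 0.0


# ---------------------------------------------------------------------------
# smoothing / evaluation


def _toy_table(centers, f, smoothing, fitted=None, counts=None,
               smoothing_range=(0.25, 0.85)):
    centers = np.asarray(centers, float)
    n_bins = centers.size
    edges = np.concatenate([[0.05], (centers[:-1] + centers[1:]) / 2, [1.0]])
    bins = brdf.NdviBinSpec(mode="static", n_bins=n_bins, lower_mask=0.05,
                            edges=edges)
    f = np.asarray(f, float)
    shape = f.shape
    return brdf.BRDFCoefficientTable(
        f_iso=f, f_geo=0.1 * f, f_vol=0.2 * f,
        se_iso=np.zeros(shape), se_geo=np.zeros(shape), se_vol=np.zeros(shape),
        bin_centers=centers,
        bin_counts=np.full(n_bins, 100) if counts is None else np.asarray(counts),
        fitted=np.ones(n_bins, bool) if fitted is None else np.asarray(fitted),
        bins=bins, smoothing=smoothing, smoothing_range=smoothing_range)


def test_interpolation_exact_at_knots():
    centers = np.array([0.3, 0.5, 0.7])
    f = np.array([[0.2], [0.35], [0.3]])
    table = _toy_table(centers, f, "linear_interpolation")
    for i, c in enumerate(centers):
        f_iso, _, _ = brdf.coefficients_at_ndvi(table, c)
        assert f_iso[0] == pytest.approx(f[i, 0], abs=1e-15)


def test_regression_equals_interpolation_for_collinear_knots():
    centers = np.array([0.3, 0.45, 0.6, 0.75])
    f = (0.1 + 0.4 * centers)[:, None]
    t_interp = _toy_table(centers, f, "linear_interpolation")
    t_reg = _toy_table(centers, f, "linear_regression")
    t_wreg = _toy_table(centers, f, "weighted_linear_regression",
                        counts=[10, 400, 30, 200])
    grid = np.linspace(0.3, 0.75, 40)
    a = brdf.coefficients_at_ndvi(t_interp, grid)[0]
    b = brdf.coefficients_at_ndvi(t_reg, grid)[0]
    c = brdf.coefficients_at_ndvi(t_wreg, grid)[0]
    np.testing.assert_allclose(a, b, atol=1e-12)
    np.testing.assert_allclose(a, c, atol=1e-12)


def test_constant_extension_above_smoothing_range():
    centers = np.array([0.3, 0.5, 0.8])
    f = np.array([[0.2], [0.3], [0.4]])
    table = _toy_table(centers, f, "linear_interpolation")
    hi = brdf.coefficients_at_ndvi(table, 0.95)[0]
    knot = brdf.coefficients_at_ndvi(table, 0.8)[0]
    np.testing.assert_allclose(hi, knot)
    lo = brdf.coefficients_at_ndvi(table, 0.06)[0]
    np.testing.assert_allclose(lo, brdf.coefficients_at_ndvi(table, 0.3)[0])


def test_regression_clamped_to_smoothing_range():
    centers = np.array([0.3, 0.5, 0.7])
    f = (0.1 + 0.4 * centers)[:, None]
    table = _toy_table(centers, f, "linear_regression")
    np.testing.assert_allclose(brdf.coefficients_at_ndvi(table, 0.99)[0],
                               brdf.coefficients_at_ndvi(table, 0.85)[0])


def test_smoothing_none_uses_containing_bin_and_nearest_for_unfit():
    centers = np.array([0.2, 0.5, 0.8])
    f = np.array([[0.1], [0.2], [0.3]])
    table = _toy_table(centers, f, "none", fitted=[True, False, True])
    # containing bin fitted
    assert brdf.coefficients_at_ndvi(table, 0.2)[0][0] == pytest.approx(0.1)
    # middle bin unfitted: nearest fitted center (0.2 vs 0.8 from 0.45 -> 0.2)
    assert brdf.coefficients_at_ndvi(table, 0.45)[0][0] == pytest.approx(0.1)
    assert brdf.coefficients_at_ndvi(table, 0.7)[0][0] == pytest.approx(0.3)


def test_ndvi_below_mask_rejected():
    table = _toy_table(np.array([0.3, 0.6]), np.array([[0.1], [0.2]]), "none")
    with pytest.raises(DataError):
        brdf.coefficients_at_ndvi(table, 0.01)


def test_interpolation_continuity_at_bin_edges():
    centers = np.linspace(0.28, 0.82, 10)
    rng = np.random.default_rng(0)
    f = rng.uniform(0.1, 0.5, (10, 3))
    table = _toy_table(centers, f, "linear_interpolation")
    for edge in table.bins.edges[1:-1]:
        below = brdf.coefficients_at_ndvi(table, np.nextafter(edge, 0.0))
        above = brdf.coefficients_at_ndvi(table, np.nextafter(edge, 1.0))
        for lo, hi in zip(below, above):
            assert np.max(np.abs(hi - lo)) < 1e-12


# ---------------------------------------------------------------------------
# prediction / application


def test_predict_trivials():
    assert brdf.predict_brdf(0.3, 0.6, 1.0, 0.4, 0.0, 0.0) == pytest.approx(0.4)
    assert brdf.predict_brdf(0.0, 0.0, 0.7, 0.4, 0.05, 0.1) == pytest.approx(0.4)


def test_predict_matches_kernel_oracle():
    ts, tv, phi = np.radians(30.0), np.radians(20.0), np.radians(90.0)
    expected = 0.3 + 0.005 * li_scalar(ts, tv, phi) + 0.1 * ross_scalar(ts, tv, phi)
    assert brdf.predict_brdf(tv, ts, phi, 0.3, 0.005, 0.1) == pytest.approx(
        expected, abs=1e-12)


def _apply_setup(exact_group, exact_table, line=0):
    cube, obs, nd = exact_group[line]
    return cube, obs, nd, exact_table


def test_apply_low_ndvi_pixels_retained(exact_group, exact_table):
    cube, obs, nd = exact_group[0]
    nd2 = nd.copy()
    nd2[10, 10] = 0.02
    out = brdf.apply_brdf_correction(cube, obs, nd2, exact_table)
    np.testing.assert_array_equal(out.values[:, 10, 10], cube.values[:, 10, 10])
    assert not np.allclose(out.values[:, 20, 20], cube.values[:, 20, 20])


def test_apply_nadir_identity_without_reference(exact_table):
    """theta_v = 0 pixels are unchanged when no reference zenith is used."""
    # odd column count puts a true-nadir column in the swath
    spec = SyntheticSceneSpec(n_lines=1, n_rows=40, n_cols=41,
                              ndvi_field="discrete", terrain="flat", seed=6)
    lines, _ = generate_group(spec)
    cube, obs = lines[0]
    nd = brdf.compute_ndvi(cube)
    out = brdf.apply_brdf_correction(cube, obs, nd, exact_table,
                                     reference_zenith=None)
    nadir = obs.sensor_zenith == 0.0
    assert nadir.any()
    np.testing.assert_allclose(out.values[:, nadir], cube.values[:, nadir],
                               rtol=0, atol=1e-15)


def test_apply_single_pixel_ratio_oracle(exact_group, exact_table):
    cube, obs, nd = exact_group[0]
    out = brdf.apply_brdf_correction(cube, obs, nd, exact_table)
    r, c = 7, 13
    f_iso, f_geo, f_vol = brdf.coefficients_at_ndvi(exact_table, nd[r, c])
    ts = np.radians(obs.solar_zenith[r, c])
    tv = np.radians(obs.sensor_zenith[r, c])
    d = abs(obs.solar_azimuth[r, c] - obs.sensor_azimuth[r, c]) % 360
    phi = np.radians(360 - d if d > 180 else d)
    ts_ref = np.radians(exact_table.reference_zenith)
    for band in range(cube.header.n_bands):
        rho_obs = 0.0 + brdf.predict_brdf(tv, ts, phi,
                                          f_iso[band], f_geo[band], f_vol[band])
        rho_nad = brdf.predict_brdf(0.0, ts_ref, 0.0,
                                    f_iso[band], f_geo[band], f_vol[band])
        expected = cube.values[band, r, c] * rho_nad / rho_obs
        assert out.values[band, r, c] == pytest.approx(expected, abs=1e-12)


def test_apply_phi_n_invariance(exact_group, exact_table, monkeypatch):
    """The arbitrary nadir-term azimuth phi_n does not change the output."""
    cube, obs, nd = exact_group[0]
    reference = brdf.apply_brdf_correction(cube, obs, nd, exact_table)
    for phi_n in (0.5, np.pi / 2, 3.0):
        monkeypatch.setattr(brdf, "PHI_N", phi_n)
        other = brdf.apply_brdf_correction(cube, obs, nd, exact_table)
        assert np.max(np.abs(other.values - reference.values)) < 1e-12


def test_apply_band_count_mismatch(exact_group, exact_table):
    cube, obs, nd = exact_group[0]
    small = envi.ReflectanceCube(
        envi.SceneHeader(n_rows=cube.header.n_rows, n_cols=cube.header.n_cols,
                         n_bands=2, wavelengths=np.array([665.0, 850.0])),
        cube.values[2:4], cube.valid_mask)
    with pytest.raises(DataError):
        brdf.apply_brdf_correction(small, obs, nd, exact_table)


# ---------------------------------------------------------------------------
# sidecar


def test_model_sidecar_roundtrip(tmp_path, exact_table):
    path = tmp_path / "model.json"
    brdf.save_model(exact_table, path, extra={"topo_fits": {}})
    back, extra = brdf.load_model(path)
    np.testing.assert_array_equal(back.f_iso, exact_table.f_iso)
    np.testing.assert_array_equal(back.bins.edges, exact_table.bins.edges)
    assert back.kernel_choice == exact_table.kernel_choice
    assert back.reference_zenith == exact_table.reference_zenith
    assert extra == {"topo_fits": {}}
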