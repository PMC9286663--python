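"""Synthetic flightline groups with known BRDF, terrain and geometry truth.

The generator emulates the structure of an airborne flight box: several
long, narrow, overlapping strips imaged across a multi-hour solar window.
Each line shares a single world-coordinate surface (NDVI pattern, terrain,
per-NDVI BRDF coefficients), so overlapping pixels are exactly co-registered
views of the same target under different sun/view geometry.

Forward model, per pixel and band:

    rho = f_iso(n) * (1 + g(n) K_geo + v(n) K_vol)        directional term
    R   = rho * (cos i + C) / (cos a cos theta_s + C)     terrain modulation
    R  += Gaussian noise

where n is the surface NDVI.  Two deliberate simplifications make the truth
analytically recoverable:

* the anisotropy ratios g(n) = f_geo/f_iso and v(n) = f_vol/f_iso are the
  same for every band, which makes the ratio index NDVI exactly invariant
  to the directional term (NDVI of rho equals NDVI of f_iso);
* the two NDVI-defining bands are generated as s(1 - n) and s(1 + n), so
  the index computed from the cube reproduces the intended field to float
  precision on flat terrain.

``ndvi_field="discrete"`` quantizes the surface to a fixed set of NDVI
levels; with fitting bins centered on those levels the per-bin constant
coefficient model is exactly true, which is the configuration in which
noiseless fits recover the truth to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .envi import MapInfo, ObservationStack, ReflectanceCube, SceneHeader
from .errors import ConfigurationError
from .kernels import KernelChoice, KernelShapeConstants, kernels_at
from .solar import relative_azimuth
from .topo import illumination_factor, terrain_relative_azimuth

DEFAULT_WAVELENGTHS = np.array(
    [480.0, 560.0, 665.0, 850.0, 975.0, 1050.0, 1150.0, 1240.0, 1650.0, 2215.0]
)


@dataclass
class SyntheticSceneSpec:
    n_lines: int = 3
    n_rows: int = 120
    n_cols: int = 80
    overlap_fraction: float = 0.3
    pixel_size: float = 15.0  # m
    wavelengths: np.ndarray = field(default_factory=lambda: DEFAULT_WAVELENGTHS.copy())
    solar_zenith: tuple | None = None  # degrees per line; default 25..50 sweep
    solar_azimuth: tuple | None = None  # degrees per line
    view_sweep_deg: float = 17.5  # max cross-track view zenith
    terrain: str = "flat"  # or "hills"
    hill_amplitude: float = 80.0  # m
    hill_wavelength: float = 900.0  # m
    ndvi_field: str = "smooth"  # or "discrete"
    ndvi_range: tuple = (0.08, 0.88)
    ndvi_levels: np.ndarray | None = None  # discrete mode; default 6 levels
    patch_pixels: int = 3  # patch size of the discrete checkerboard
    brightness_scale: float = 0.25  # s in the NDVI-band construction
    # Anisotropy ratios g(n) = f_geo/f_iso, v(n) = f_vol/f_iso.  With the
    # default b/r = 10 the Li-Sparse kernel reaches magnitudes of ~15 over a
    # +-17.5 degree sweep, so g must stay small for reflectance to remain
    # positive everywhere.
    geo_ratio: tuple = (0.008, 0.010)  # g(n) = g0 + g1 n
    vol_ratio: tuple = (0.20, 0.40)  # v(n) = v0 + v1 n
    c_truth: float | np.ndarray = 0.15  # SCS+C moderator, scalar or per band
    noise_sigma: float = 0.0
    mask_fraction: float = 0.0
    kernel_choice: KernelChoice = field(default_factory=KernelChoice)
    kernel_constants: KernelShapeConstants = field(default_factory=KernelShapeConstants)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ConfigurationError("overlap_fraction must lie in [0, 1)")
        if self.n_lines > 1:
            if int(round(self.n_cols * self.overlap_fraction)) < 1:
                raise ConfigurationError(
                    "overlap_fraction too small: adjacent lines share no column")
        if self.terrain not in ("flat", "hills"):
            raise ConfigurationError(f"unknown terrain mode {self.terrain!r}")
        if self.ndvi_field not in ("smooth", "discrete"):
            raise ConfigurationError(f"unknown ndvi_field mode {self.ndvi_field!r}")
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.solar_zenith is None:
            self.solar_zenith = tuple(np.linspace(25.0, 50.0, self.n_lines))
        if self.solar_azimuth is None:
            self.solar_azimuth = tuple(
                np.mod(np.linspace(130.0, 230.0, self.n_lines), 360.0))
        if self.ndvi_field == "discrete" and self.ndvi_levels is None:
            self.ndvi_levels = np.linspace(0.15, 0.85, 6)

    @property
    def n_bands(self):
        return self.wavelengths.size

    @property
    def step_cols(self):
        return int(round(self.n_cols * (1.0 - self.overlap_fraction)))


@dataclass
class TruthRecord:
    """Generator bookkeeping sufficient to evaluate truth coefficients."""

    spec: SyntheticSceneSpec
    iso_base: np.ndarray  # (n_bands,)
    iso_slope: np.ndarray  # (n_bands,)
    solar_zenith: np.ndarray  # per line, degrees
    solar_azimuth: np.ndarray
    pooled_solar_zenith_mean: float
    ndvi: list  # per-line intended NDVI rasters
    line_offsets_cols: np.ndarray
    overlap_cols: list  # per adjacent pair: (a_lo, a_hi) in line a's grid

    def coefficients_at(self, ndvi):
        """Truth (f_iso, f_geo, f_vol), each ``ndvi.shape + (n_bands,)``."""
        n = np.asarray(ndvi, dtype=float)[..., None]
        f_iso = self.iso_base + self.iso_slope * n
        g0, g1 = self.spec.geo_ratio
        v0, v1 = self.spec.vol_ratio
        return f_iso, f_iso * (g0 + g1 * n), f_iso * (v0 + v1 * n)

    def to_dict(self):
        return {
            "iso_base": self.iso_base.tolist(),
            "iso_slope": self.iso_slope.tolist(),
            "geo_ratio": list(self.spec.geo_ratio),
            "vol_ratio": list(self.spec.vol_ratio),
            "solar_zenith": self.solar_zenith.tolist(),
            "solar_azimuth": self.solar_azimuth.tolist(),
            "pooled_solar_zenith_mean": self.pooled_solar_zenith_mean,
            "line_offsets_cols": self.line_offsets_cols.tolist(),
            "overlap_cols": [list(map(int, oc)) for oc in self.overlap_cols],
            "noise_sigma": self.spec.noise_sigma,
            "seed": self.spec.seed,
        }


def _iso_spectrum_params(spec: SyntheticSceneSpec):
    """(base, slope) per band of f_iso(n) = base + slope * n.

    The 665 and 850 nm bands are pinned to s(1 -/+ n) so the cube's NDVI is
    the intended field; other bands get smooth, positive spectra.
    """
    wl = spec.wavelengths
    s = spec.brightness_scale
    base = 0.18 + 0.08 * np.sin(2 * np.pi * wl / 1800.0)
    slope = 0.08 * np.sin(2 * np.pi * wl / 2300.0 + 1.0)
    red = int(np.argmin(np.abs(wl - 665.0)))
    nir = int(np.argmin(np.abs(wl - 850.0)))
    base[red], slope[red] = s, -s
    base[nir], slope[nir] = s, +s
    return base, slope


def _ndvi_surface(spec: SyntheticSceneSpec, x, y):
    """Intended NDVI at world coordinates (meters)."""
    if spec.ndvi_field == "smooth":
        lo, hi = spec.ndvi_range
        wave = 0.5 + 0.5 * np.sin(2 * np.pi * x / 1100.0) * np.cos(2 * np.pi * y / 700.0)
        return lo + (hi - lo) * wave
    levels = np.asarray(spec.ndvi_levels, dtype=float)
    patch = spec.patch_pixels * spec.pixel_size
    idx = (np.floor(x / patch) + np.floor(y / patch)).astype(int) % levels.size
    return levels[idx]


def _terrain(spec: SyntheticSceneSpec, x, y):
    """(slope, aspect) in degrees from the analytic hill surface."""
    if spec.terrain == "flat":
        zeros = np.zeros_like(x)
        return zeros, zeros
    k = 2 * np.pi / spec.hill_wavelength
    a = spec.hill_amplitude
    zx = a * k * np.cos(k * x) * np.cos(k * y)
    zy = -a * k * np.sin(k * x) * np.sin(k * y)
    slope = np.degrees(np.arctan(np.hypot(zx, zy)))
    aspect = np.mod(np.degrees(np.arctan2(-zx, -zy)), 360.0)
    return slope, aspect


def generate_group(spec: SyntheticSceneSpec):
    """Generate the flightline group.

    Returns ``(lines, truth)`` where ``lines`` is a list of
    ``(ReflectanceCube, ObservationStack)`` and ``truth`` a
    :class:`TruthRecord`.
    """
    rng = np.random.default_rng(spec.seed)
    base, slope_par = _iso_spectrum_params(spec)
    c_truth = np.broadcast_to(np.asarray(spec.c_truth, dtype=float),
                              (spec.n_bands,)).copy()

    rows = np.arange(spec.n_rows)
    cols = np.arange(spec.n_cols)
    half = (spec.n_cols - 1) / 2.0
    signed = (cols - half) / max(half, 1.0)
    theta_v_row = spec.view_sweep_deg * np.abs(signed)
    # sensor azimuth flips by 180 degrees across nadir (whiskbroom sweep)
    phi_v_row = np.where(signed >= 0, 90.0, 270.0)

    offsets = np.arange(spec.n_lines) * spec.step_cols
    lines, ndvi_truth = [], []
    zen_sum = 0.0
    zen_n = 0
    for i in range(spec.n_lines):
        ulx = offsets[i] * spec.pixel_size
        x = ulx + (cols + 0.5) * spec.pixel_size
        y = -(rows + 0.5) * spec.pixel_size
        xg, yg = np.meshgrid(x, y)
        n = _ndvi_surface(spec, xg, yg)
        slope_deg, aspect_deg = _terrain(spec, xg, yg)

        theta_s = np.full((spec.n_rows, spec.n_cols), float(spec.solar_zenith[i]))
        phi_s = np.full_like(theta_s, float(spec.solar_azimuth[i]))
        theta_v = np.broadcast_to(theta_v_row, theta_s.shape).copy()
        phi_v = np.broadcast_to(phi_v_row, theta_s.shape).copy()

        phi = np.radians(relative_azimuth(phi_s, phi_v))
        k_geo, k_vol = kernels_at(np.radians(theta_s), np.radians(theta_v), phi,
                                  spec.kernel_choice, spec.kernel_constants)
        g0, g1 = spec.geo_ratio
        v0, v1 = spec.vol_ratio
        modulation = 1.0 + (g0 + g1 * n) * k_geo + (v0 + v1 * n) * k_vol
        f_iso = base[:, None, None] + slope_par[:, None, None] * n[None]
        values = f_iso * modulation[None]

        if spec.terrain == "hills":
            alpha = np.radians(slope_deg)
            ts = np.radians(theta_s)
            phi_t = np.radians(terrain_relative_azimuth(phi_s, aspect_deg))
            cos_i = illumination_factor(alpha, ts, phi_t)
            scs = np.cos(alpha) * np.cos(ts)
            values = values * ((cos_i + c_truth[:, None, None])
                               / (scs + c_truth[:, None, None]))
        if spec.noise_sigma > 0:
            values = values + rng.normal(0.0, spec.noise_sigma, values.shape)

        valid = np.ones(theta_s.shape, dtype=bool)
        if spec.mask_fraction > 0:
            valid &= rng.random(valid.shape) >= spec.mask_fraction

        map_info = MapInfo(ulx=ulx, uly=0.0, x_size=spec.pixel_size,
                           y_size=spec.pixel_size)
        header = SceneHeader(
            n_rows=spec.n_rows, n_cols=spec.n_cols, n_bands=spec.n_bands,
            wavelengths=spec.wavelengths.copy(), interleave="bil",
            map_info=map_info,
        )
        cube = ReflectanceCube(header, values, valid)
        obs = ObservationStack(
            sensor_zenith=theta_v, sensor_azimuth=phi_v,
            solar_zenith=theta_s, solar_azimuth=phi_s,
            slope=slope_deg, aspect=aspect_deg,
            valid_mask=valid.copy(), map_info=map_info,
        )
        lines.append((cube, obs))
        ndvi_truth.append(n)
        zen_sum += float(theta_s[valid].sum())
        zen_n += int(valid.sum())

    overlap_cols = []
    for i in range(spec.n_lines - 1):
        a_lo = offsets[i + 1] - offsets[i]
        overlap_cols.append((int(a_lo), int(spec.n_cols)))

    truth = TruthRecord(
        spec=spec, iso_base=base, iso_slope=slope_par,
        solar_zenith=np.asarray(spec.solar_zenith, dtype=float),
        solar_azimuth=np.asarray(spec.solar_azimuth, dtype=float),
        pooled_solar_zenith_mean=zen_sum / zen_n,
        ndvi=ndvi_truth, line_offsets_cols=offsets,
        overlap_cols=overlap_cols,
    )
    return lines, truth


def hillside_calibration_scene(a, b, theta_s_deg=40.0, n_rows=60, n_cols=60,
                               wavelengths=None, seed=0):
    """Scene in which reflectance is exactly ``a + b cos i`` per band.

    Slopes and aspects vary smoothly over the grid, so the illumination
    factor spans a wide range and the per-band linear fit is well posed.
    Used to verify SCS+C parameter recovery.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if wavelengths is None:
        wavelengths = DEFAULT_WAVELENGTHS[: a.size]
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    slope = 5.0 + 35.0 * (0.5 + 0.5 * np.sin(rows / 7.0) * np.cos(cols / 5.0))
    aspect = np.mod(37.0 + 360.0 * cols / n_cols + 15.0 * np.sin(rows / 9.0), 360.0)
    theta_s = np.full(slope.shape, float(theta_s_deg))
    phi_s = np.full(slope.shape, 150.0)
    cos_i = illumination_factor(
        np.radians(slope), np.radians(theta_s),
        np.radians(terrain_relative_azimuth(phi_s, aspect)))
    values = a[:, None, None] + b[:, None, None] * cos_i[None]
    valid = np.ones(slope.shape, dtype=bool)
    header = SceneHeader(n_rows=n_rows, n_cols=n_cols, n_bands=a.size,
                         wavelengths=np.asarray(wavelengths, dtype=float),
                         interleave="bsq")
    cube = ReflectanceCube(header, values, valid)
    obs = ObservationStack(
        sensor_zenith=np.zeros(slope.shape), sensor_azimuth=np.full(slope.shape, 90.0),
        solar_zenith=theta_s, solar_azimuth=phi_s,
        slope=slope, aspect=aspect, valid_mask=valid.copy(),
    )
    return cube, obs, cos_i


def truth_report(truth: TruthRecord, table):
    """Absolute coefficient error per band per fitted bin, truth evaluated
    at the bin center."""
    centers = table.bin_centers
    t_iso, t_geo, t_vol = truth.coefficients_at(centers)  # (n_bins, n_bands)
    errors = {
        "f_iso": np.abs(table.f_iso - t_iso),
        "f_geo": np.abs(table.f_geo - t_geo),
        "f_vol": np.abs(table.f_vol - t_vol),
    }
    for key in errors:
        errors[key][~table.fitted] = np.nan
    errors["max_abs_error"] = float(
        np.nanmax([np.nanmax(errors[k]) for k in ("f_iso", "f_geo", "f_vol")])
    )
    return errors
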