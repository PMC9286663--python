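"""Group-level, NDVI-stratified kernel BRDF fitting and correction.

The engine stratifies the pooled pixels of a flightline group into NDVI
bins, draws a stratified random sample across all lines, fits the linear
kernel model

    rho = f_iso + f_geo * K_geo + f_vol * K_vol

per band and per bin by ordinary least squares, optionally smooths the
coefficients across bins (so corrected imagery has no seams at bin
boundaries), and applies the multiplicative normalization

    R_out = R_t * rho(0, theta_ref, phi_n) / rho(theta_v, theta_s, phi)

which moves every pixel to nadir view and, when a reference solar zenith is
given, to a common illumination angle.  Pixels below the NDVI mask threshold
(water, bare soil, anomalous values) retain their input reflectance.

phi_n, the relative azimuth of the modeled nadir term, is fixed to 0: at
nadir view both kernels are analytically independent of azimuth, so the
choice is immaterial (covered by a property test).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, DataError
from .kernels import KernelChoice, KernelShapeConstants, kernels_at
from .solar import relative_azimuth

NDVI_RED_NM = 665.0
NDVI_NIR_NM = 850.0
BAND_MATCH_TOL_NM = 20.0
PHI_N = 0.0  # radians; arbitrary by nadir azimuth-independence
RHO_GUARD = 1e-6

SMOOTHING_MODES = ("none", "linear_regression", "weighted_linear_regression",
                   "linear_interpolation")


# ---------------------------------------------------------------------------
# NDVI


def nearest_band(wavelengths, target_nm, tol_nm=BAND_MATCH_TOL_NM):
    """Index of the band nearest ``target_nm``; error if farther than tol."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    idx = int(np.argmin(np.abs(wavelengths - target_nm)))
    if abs(wavelengths[idx] - target_nm) > tol_nm:
        raise ConfigurationError(
            f"no band within {tol_nm} nm of {target_nm} nm "
            f"(nearest: {wavelengths[idx]:.1f} nm)"
        )
    return idx


def compute_ndvi(cube):
    """Per-pixel NDVI (R850 - R665) / (R850 + R665); NaN where undefined."""
    if cube.header.wavelengths is None:
        raise ConfigurationError("cube has no wavelength list; cannot locate NDVI bands")
    nir = cube.values[nearest_band(cube.header.wavelengths, NDVI_NIR_NM)]
    red = cube.values[nearest_band(cube.header.wavelengths, NDVI_RED_NM)]
    total = nir + red
    ndvi = np.full(total.shape, np.nan)
    ok = cube.valid_mask & (total > 0)
    ndvi[ok] = (nir[ok] - red[ok]) / total[ok]
    return ndvi


# ---------------------------------------------------------------------------
# binning


@dataclass
class NdviBinSpec:
    """NDVI stratification: equal-width static bins or equal-count dynamic
    bins built from the pooled group sample."""

    mode: str = "dynamic"
    n_bins: int = 18
    lower_mask: float = 0.05
    dynamic_upper: float = 0.9
    edges: np.ndarray | None = None

    def __post_init__(self):
        if self.mode not in ("static", "dynamic"):
            raise ConfigurationError(f"unknown bin mode {self.mode!r}")
        if self.n_bins < 1:
            raise ConfigurationError("n_bins must be >= 1")
        if self.edges is not None:
            e = np.asarray(self.edges, dtype=float)
            if e.size != self.n_bins + 1:
                raise ConfigurationError("edges length must be n_bins + 1")
            if not np.all(np.diff(e) > 0):
                raise ConfigurationError("edges must be strictly increasing")
            if e[0] != self.lower_mask:
                raise ConfigurationError("first edge must equal lower_mask")
            self.edges = e

    @property
    def centers(self):
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def build_bins(ndvi_values, spec: NdviBinSpec) -> NdviBinSpec:
    """Derive bin edges.  Static: equal width over [lower_mask, 1.0].
    Dynamic: equal-count quantiles of the pooled sample restricted to
    (lower_mask, dynamic_upper), last bin extended to 1.0."""
    if spec.mode == "static":
        edges = np.linspace(spec.lower_mask, 1.0, spec.n_bins + 1)
        return replace(spec, edges=edges)
    vals = np.asarray(ndvi_values, dtype=float)
    vals = vals[np.isfinite(vals) & (vals > spec.lower_mask) & (vals < spec.dynamic_upper)]
    if vals.size == 0:
        raise DataError("no NDVI values above the mask threshold for dynamic binning")
    n_distinct = np.unique(vals).size
    if n_distinct < spec.n_bins:
        raise DataError(
            f"only {n_distinct} distinct NDVI values; at most {n_distinct} "
            f"dynamic bins achievable (requested {spec.n_bins})"
        )
    q = np.linspace(0.0, 1.0, spec.n_bins + 1)
    edges = np.quantile(vals, q)
    edges[0] = spec.lower_mask
    edges[-1] = 1.0
    if not np.all(np.diff(edges) > 0):
        raise DataError("dynamic bin edges collapse; NDVI distribution too discrete")
    return replace(spec, edges=edges)


def assign_bins(ndvi, spec: NdviBinSpec):
    """Bin index per pixel; -1 for masked / below-threshold / NaN pixels.

    Bins are right-open [e_i, e_{i+1}) except the last, closed at 1.0.
    """
    if spec.edges is None:
        raise ConfigurationError("bin edges not built; call build_bins first")
    ndvi = np.asarray(ndvi, dtype=float)
    idx = np.searchsorted(spec.edges, ndvi, side="right") - 1
    idx = np.where(ndvi == spec.edges[-1], spec.n_bins - 1, idx)
    bad = ~np.isfinite(ndvi) | (ndvi < spec.edges[0]) | (ndvi > spec.edges[-1])
    return np.where(bad, -1, np.clip(idx, 0, spec.n_bins - 1)).astype(int)


# ---------------------------------------------------------------------------
# sampling


@dataclass
class SampleSet:
    """Stratified random sample pooled across the flightline group."""

    reflectance: np.ndarray  # (n_samples, n_bands), topo-corrected
    theta_s: np.ndarray  # radians
    theta_v: np.ndarray  # radians
    phi: np.ndarray  # radians, folded [0, pi]
    ndvi: np.ndarray
    bin_id: np.ndarray
    line_id: np.ndarray
    seed: int

    @property
    def n_samples(self):
        return self.reflectance.shape[0]


def stratified_group_sample(group, bins: NdviBinSpec, per_bin: int,
                            seed: int) -> SampleSet:
    """Draw up to ``per_bin`` pixels per NDVI bin, uniformly at random from
    the pooled valid pixels of all lines.

    Each line's contribution to a bin is therefore proportional to its
    eligible area, which is what makes the fit a group fit.  Bins with no
    eligible pixels are simply absent from the sample (flagged later as
    unfitted and covered by smoothing).

    ``group`` is a list of (cube, obs, ndvi) triples; the cube should carry
    topographically corrected reflectance.
    """
    if not group:
        raise DataError("empty flightline group")
    pooled = []
    for line_id, (cube, obs, ndvi) in enumerate(group):
        ok = cube.valid_mask & obs.valid_mask & np.isfinite(ndvi)
        b = assign_bins(ndvi, bins)
        ok &= b >= 0
        rows, cols = np.nonzero(ok)
        pooled.append((line_id, rows, cols, b[rows, cols], ndvi[rows, cols]))
    line_ids = np.concatenate([np.full(r.size, lid) for lid, r, *_ in pooled])
    rows = np.concatenate([r for _, r, *_ in pooled])
    cols = np.concatenate([c for _, _, c, *_ in pooled])
    bin_ids = np.concatenate([b for *_, b, _ in pooled])
    ndvis = np.concatenate([n for *_, n in pooled])
    if rows.size == 0:
        raise DataError("no eligible pixels in any bin")

    rng = np.random.default_rng(seed)
    chosen = []
    for bin_id in range(bins.n_bins):
        members = np.nonzero(bin_ids == bin_id)[0]
        if members.size == 0:
            continue
        if members.size > per_bin:
            members = rng.choice(members, size=per_bin, replace=False)
        chosen.append(np.sort(members))
    chosen = np.concatenate(chosen)

    refl = np.empty((chosen.size, group[0][0].header.n_bands))
    theta_s = np.empty(chosen.size)
    theta_v = np.empty(chosen.size)
    phi = np.empty(chosen.size)
    for line_id, (cube, obs, _) in enumerate(group):
        sel = np.nonzero(line_ids[chosen] == line_id)[0]
        if sel.size == 0:
            continue
        r, c = rows[chosen[sel]], cols[chosen[sel]]
        refl[sel] = cube.values[:, r, c].T
        theta_s[sel] = np.radians(obs.solar_zenith[r, c])
        theta_v[sel] = np.radians(obs.sensor_zenith[r, c])
        phi[sel] = np.radians(
            relative_azimuth(obs.solar_azimuth[r, c], obs.sensor_azimuth[r, c])
        )
    return SampleSet(
        reflectance=refl, theta_s=theta_s, theta_v=theta_v, phi=phi,
        ndvi=ndvis[chosen], bin_id=bin_ids[chosen],
        line_id=line_ids[chosen], seed=int(seed),
    )


# ---------------------------------------------------------------------------
# fitting


@dataclass
class BRDFCoefficientTable:
    """Fitted kernel weights per band per NDVI bin, plus everything needed to
    re-apply the correction bit-identically."""

    f_iso: np.ndarray  # (n_bins, n_bands)
    f_geo: np.ndarray
    f_vol: np.ndarray
    se_iso: np.ndarray  # OLS standard errors, same shape (NaN if unfitted)
    se_geo: np.ndarray
    se_vol: np.ndarray
    bin_centers: np.ndarray  # (n_bins,)
    bin_counts: np.ndarray  # (n_bins,) samples used per bin
    fitted: np.ndarray  # (n_bins,) bool
    bins: NdviBinSpec
    kernel_choice: KernelChoice = field(default_factory=KernelChoice)
    kernel_constants: KernelShapeConstants = field(default_factory=KernelShapeConstants)
    smoothing: str = "none"
    smoothing_range: tuple = (0.25, 0.85)
    reference_zenith: float | None = None
    wavelengths: np.ndarray | None = None
    seed: int | None = None

    @property
    def n_bins(self):
        return self.f_iso.shape[0]

    @property
    def n_bands(self):
        return self.f_iso.shape[1]

    # -- serialization -----------------------------------------------------

    def to_dict(self):
        return {
            "f_iso": self.f_iso.tolist(),
            "f_geo": self.f_geo.tolist(),
            "f_vol": self.f_vol.tolist(),
            "se_iso": self.se_iso.tolist(),
            "se_geo": self.se_geo.tolist(),
            "se_vol": self.se_vol.tolist(),
            "bin_centers": self.bin_centers.tolist(),
            "bin_counts": self.bin_counts.tolist(),
            "fitted": self.fitted.astype(int).tolist(),
            "bin_mode": self.bins.mode,
            "bin_edges": self.bins.edges.tolist(),
            "lower_mask": self.bins.lower_mask,
            "dynamic_upper": self.bins.dynamic_upper,
            "kernel_geometric": self.kernel_choice.geometric,
            "kernel_volumetric": self.kernel_choice.volumetric,
            "b_over_r": self.kernel_constants.b_over_r,
            "h_over_b": self.kernel_constants.h_over_b,
            "smoothing": self.smoothing,
            "smoothing_range": list(self.smoothing_range),
            "reference_zenith": self.reference_zenith,
            "wavelengths": None if self.wavelengths is None else self.wavelengths.tolist(),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d):
        edges = np.asarray(d["bin_edges"], dtype=float)
        bins = NdviBinSpec(
            mode=d["bin_mode"], n_bins=edges.size - 1,
            lower_mask=d["lower_mask"], dynamic_upper=d["dynamic_upper"],
            edges=edges,
        )
        return cls(
            f_iso=np.asarray(d["f_iso"], dtype=float),
            f_geo=np.asarray(d["f_geo"], dtype=float),
            f_vol=np.asarray(d["f_vol"], dtype=float),
            se_iso=np.asarray(d["se_iso"], dtype=float),
            se_geo=np.asarray(d["se_geo"], dtype=float),
            se_vol=np.asarray(d["se_vol"], dtype=float),
            bin_centers=np.asarray(d["bin_centers"], dtype=float),
            bin_counts=np.asarray(d["bin_counts"], dtype=int),
            fitted=np.asarray(d["fitted"], dtype=bool),
            bins=bins,
            kernel_choice=KernelChoice(d["kernel_geometric"], d["kernel_volumetric"]),
            kernel_constants=KernelShapeConstants(d["b_over_r"], d["h_over_b"]),
            smoothing=d["smoothing"],
            smoothing_range=tuple(d["smoothing_range"]),
            reference_zenith=d["reference_zenith"],
            wavelengths=None if d["wavelengths"] is None
            else np.asarray(d["wavelengths"], dtype=float),
            seed=d["seed"],
        )


MIN_BIN_SAMPLES = 3
RANK_RCOND = 1e-10


def fit_brdf_coefficients(samples: SampleSet, bins: NdviBinSpec,
                          choice: KernelChoice = KernelChoice(),
                          constants: KernelShapeConstants = KernelShapeConstants(),
                          smoothing: str = "none",
                          smoothing_range=(0.25, 0.85),
                          reference_zenith: float | None = None,
                          wavelengths=None) -> BRDFCoefficientTable:
    """Per-band, per-bin OLS of reflectance on [1, K_geo, K_vol].

    Bins with too few samples or a rank-deficient kernel design are flagged
    unfitted; :func:`coefficients_at_ndvi` covers them via smoothing (or
    nearest fitted bin when smoothing is off).
    """
    if smoothing not in SMOOTHING_MODES:
        raise ConfigurationError(f"unknown smoothing mode {smoothing!r}")
    n_bands = samples.reflectance.shape[1]
    n_bins = bins.n_bins
    k_geo, k_vol = kernels_at(samples.theta_s, samples.theta_v, samples.phi,
                              choice, constants)
    shape = (n_bins, n_bands)
    f_iso = np.full(shape, np.nan)
    f_geo = np.full(shape, np.nan)
    f_vol = np.full(shape, np.nan)
    se_iso = np.full(shape, np.nan)
    se_geo = np.full(shape, np.nan)
    se_vol = np.full(shape, np.nan)
    fitted = np.zeros(n_bins, dtype=bool)
    counts = np.zeros(n_bins, dtype=int)
    centers = bins.centers.astype(float).copy()

    for bin_id in range(n_bins):
        sel = samples.bin_id == bin_id
        n = int(sel.sum())
        counts[bin_id] = n
        if n < MIN_BIN_SAMPLES:
            continue
        design = np.column_stack([np.ones(n), k_geo[sel], k_vol[sel]])
        if np.linalg.matrix_rank(design, tol=None) < 3:
            continue
        y = samples.reflectance[sel]
        beta, _, _, sv = np.linalg.lstsq(design, y, rcond=None)
        if sv.min() < RANK_RCOND * sv.max():
            continue
        resid = y - design @ beta
        dof = max(n - 3, 1)
        sigma2 = (resid**2).sum(axis=0) / dof
        xtx_inv = np.linalg.inv(design.T @ design)
        se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
        f_iso[bin_id], f_geo[bin_id], f_vol[bin_id] = beta
        se_iso[bin_id], se_geo[bin_id], se_vol[bin_id] = se
        fitted[bin_id] = True
        if bins.mode == "dynamic":
            centers[bin_id] = float(np.median(samples.ndvi[sel]))
    if not fitted.any():
        raise DataError("no NDVI bin could be fitted (all empty or rank-deficient)")

    return BRDFCoefficientTable(
        f_iso=f_iso, f_geo=f_geo, f_vol=f_vol,
        se_iso=se_iso, se_geo=se_geo, se_vol=se_vol,
        bin_centers=centers, bin_counts=counts, fitted=fitted, bins=bins,
        kernel_choice=choice, kernel_constants=constants,
        smoothing=smoothing, smoothing_range=tuple(smoothing_range),
        reference_zenith=reference_zenith,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, dtype=float),
        seed=samples.seed,
    )


# ---------------------------------------------------------------------------
# smoothing / evaluation


def _knots(table: BRDFCoefficientTable):
    """Fitted-bin centers inside the smoothing range, with their indices."""
    lo, hi = table.smoothing_range
    in_range = table.fitted & (table.bin_centers >= lo) & (table.bin_centers <= hi)
    return np.nonzero(in_range)[0]


def coefficients_at_ndvi(table: BRDFCoefficientTable, ndvi):
    """Evaluate (f_iso, f_geo, f_vol) at NDVI value(s).

    Returns three arrays of shape ``ndvi.shape + (n_bands,)``.

    * ``none``: the containing bin's constants (nearest fitted bin if the
      containing bin is unfitted).
    * ``linear_interpolation``: piecewise linear between fitted bin centers
      inside the smoothing range, constant extension outside.
    * ``linear_regression`` / ``weighted_linear_regression``: straight-line
      fit of coefficient against bin center over in-range fitted bins
      (weighted by bin sample counts for the weighted variant), evaluated at
      NDVI clamped into the range.
    """
    ndvi = np.asarray(ndvi, dtype=float)
    scalar = ndvi.ndim == 0
    ndvi = np.atleast_1d(ndvi)
    if np.any(~np.isfinite(ndvi)) or np.any(ndvi < table.bins.lower_mask):
        raise DataError("NDVI below the mask threshold passed to coefficient lookup; "
                        "caller must mask such pixels")

    coeffs = (table.f_iso, table.f_geo, table.f_vol)
    if table.smoothing == "none":
        bin_id = assign_bins(np.minimum(ndvi, table.bins.edges[-1]), table.bins)
        bin_id = np.clip(bin_id, 0, table.n_bins - 1)
        fitted_ids = np.nonzero(table.fitted)[0]
        # unfitted bins: remap to the nearest fitted bin by center distance
        remap = fitted_ids[np.argmin(
            np.abs(table.bin_centers[:, None] - table.bin_centers[fitted_ids][None, :]),
            axis=1,
        )]
        bin_id = np.where(table.fitted[bin_id], bin_id, remap[bin_id])
        out = tuple(c[bin_id] for c in coeffs)
    else:
        knot_ids = _knots(table)
        if knot_ids.size == 0:
            raise DataError("no fitted bins inside the smoothing range")
        x = table.bin_centers[knot_ids]
        order = np.argsort(x)
        x = x[order]
        if table.smoothing == "linear_interpolation" or knot_ids.size == 1:
            out = []
            for c in coeffs:
                y = c[knot_ids][order]  # (n_knots, n_bands)
                vals = np.empty(ndvi.shape + (table.n_bands,))
                for band in range(table.n_bands):
                    vals[..., band] = np.interp(ndvi, x, y[:, band])
                out.append(vals)
            out = tuple(out)
        else:
            w = None
            if table.smoothing == "weighted_linear_regression":
                w = table.bin_counts[knot_ids][order].astype(float)
            x_eval = np.clip(ndvi, table.smoothing_range[0], table.smoothing_range[1])
            out = []
            for c in coeffs:
                y = c[knot_ids][order]
                slope, intercept = _wls_line(x, y, w)
                out.append(x_eval[..., None] * slope[None, :] + intercept[None, :])
            out = tuple(out)
    if scalar:
        out = tuple(v[0] for v in out)
    return out


def _wls_line(x, y, w=None):
    """(Weighted) straight-line fit of each column of y on x."""
    if w is None:
        w = np.ones_like(x)
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w[:, None] * y).sum(axis=0) / sw
    sxx = (w * (x - xm) ** 2).sum()
    if sxx == 0.0:
        return np.zeros(y.shape[1]), ym
    slope = (w[:, None] * (x - xm)[:, None] * (y - ym)).sum(axis=0) / sxx
    return slope, ym - slope * xm


def predict_brdf(theta_v, theta_s, phi, f_iso, f_geo, f_vol,
                 choice: KernelChoice = KernelChoice(),
                 constants: KernelShapeConstants = KernelShapeConstants()):
    """Modeled reflectance rho for radian geometry and given coefficients."""
    k_geo, k_vol = kernels_at(theta_s, theta_v, phi, choice, constants)
    return f_iso + f_geo * np.asarray(k_geo) + f_vol * np.asarray(k_vol)


# ---------------------------------------------------------------------------
# application


def apply_brdf_correction(cube_t, obs, ndvi, table: BRDFCoefficientTable,
                          reference_zenith: float | None = "table"):
    """Normalize a (topographically corrected) cube to nadir view and the
    reference solar zenith.

    ``reference_zenith``: degrees, ``None`` for per-pixel solar zenith, or
    the sentinel ``"table"`` to take the value stored in the model table.
    Below-threshold NDVI pixels retain their input reflectance.
    """
    if reference_zenith == "table":
        reference_zenith = table.reference_zenith
    if (table.wavelengths is not None and cube_t.header.wavelengths is not None
            and not np.array_equal(table.wavelengths, cube_t.header.wavelengths)):
        raise DataError("model wavelength grid does not match cube")
    if table.n_bands != cube_t.header.n_bands:
        raise DataError("model band count does not match cube")

    out = cube_t.copy()
    valid = cube_t.valid_mask & obs.valid_mask & np.isfinite(ndvi)
    veg = valid & (ndvi >= table.bins.lower_mask)
    if not veg.any():
        return out
    r, c = np.nonzero(veg)
    theta_s = np.radians(obs.solar_zenith[r, c])
    theta_v = np.radians(obs.sensor_zenith[r, c])
    phi = np.radians(relative_azimuth(obs.solar_azimuth[r, c],
                                      obs.sensor_azimuth[r, c]))
    f_iso, f_geo, f_vol = coefficients_at_ndvi(table, ndvi[r, c])  # (n, n_bands)

    choice, constants = table.kernel_choice, table.kernel_constants
    kg_obs, kv_obs = kernels_at(theta_s, theta_v, phi, choice, constants)
    ts_ref = theta_s if reference_zenith is None else np.radians(reference_zenith)
    kg_nad, kv_nad = kernels_at(ts_ref, 0.0, PHI_N, choice, constants)

    rho_obs = f_iso + f_geo * np.asarray(kg_obs)[..., None] + f_vol * np.asarray(kv_obs)[..., None]
    rho_nad = f_iso + f_geo * np.asarray(kg_nad)[..., None] + f_vol * np.asarray(kv_nad)[..., None]

    guarded = np.abs(rho_obs) < RHO_GUARD
    factor = np.where(guarded, 1.0, rho_nad / np.where(guarded, 1.0, rho_obs))
    bad_pix = guarded.any(axis=1)
    if bad_pix.any():
        import logging

        logging.getLogger(__name__).warning(
            "BRDF correction: masked %d pixels with |rho_obs| < %g",
            int(bad_pix.sum()), RHO_GUARD,
        )
        out.valid_mask[r[bad_pix], c[bad_pix]] = False
    out.values[:, r, c] = (cube_t.values[:, r, c].T * factor).T
    return out


# ---------------------------------------------------------------------------
# model sidecar


def save_model(table: BRDFCoefficientTable, path, extra: dict | None = None):
    """Write the model sidecar JSON (deterministic layout)."""
    payload = table.to_dict()
    if extra:
        payload["extra"] = extra
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path):
    with open(path) as fh:
        payload = json.load(fh)
    extra = payload.pop("extra", None)
    return BRDFCoefficientTable.from_dict(payload), extra
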