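"""Sun-canopy-sensor + C (SCS+C) topographic correction.

Terrain tilts the local illumination away from the flat-surface value; the
SCS+C correction rescales each band by

    R_t = R * (cos(alpha) * cos(theta_s) + C) / (cos(i) + C)

where ``cos i = cos(alpha) cos(theta_s) + sin(alpha) sin(theta_s) cos(phi_t)``
is the illumination factor on a slope of angle alpha whose sun-terrain
relative azimuth is phi_t, and the per-band moderator C = a/b comes from an
ordinary least-squares fit of reflectance against cos i.  The correction is
applied per flightline, before any BRDF fitting.

Bands whose R-vs-cos i relation is flat (|b| below a threshold) are left
unchanged: the model cannot explain them, and forcing a correction through
a near-zero slope would only amplify noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .solar import relative_azimuth

log = logging.getLogger(__name__)

DENOM_GUARD = 1e-8


@dataclass
class TopoFit:
    """Per-band linear fit R = a + b cos i and the derived C = a/b."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    degenerate: np.ndarray  # bands where |b| < threshold; passed through
    fit_sample_size: int

    def to_dict(self):
        return {
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "c": self.c.tolist(),
            "degenerate": self.degenerate.astype(int).tolist(),
            "fit_sample_size": int(self.fit_sample_size),
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            a=np.asarray(d["a"], dtype=float),
            b=np.asarray(d["b"], dtype=float),
            c=np.asarray(d["c"], dtype=float),
            degenerate=np.asarray(d["degenerate"], dtype=bool),
            fit_sample_size=int(d["fit_sample_size"]),
        )


def illumination_factor(alpha, theta_s, phi_t):
    """cos i for slope alpha, solar zenith theta_s, sun-terrain azimuth phi_t
    (all radians)."""
    return (np.cos(alpha) * np.cos(theta_s)
            + np.sin(alpha) * np.sin(theta_s) * np.cos(phi_t))


def terrain_relative_azimuth(solar_azimuth_deg, aspect_deg):
    """phi_t = sun azimuth minus terrain aspect, folded into [0, 180] deg."""
    return relative_azimuth(np.mod(solar_azimuth_deg, 360.0),
                            np.mod(aspect_deg, 360.0))


def _cos_i_field(obs):
    alpha = np.radians(obs.slope)
    theta_s = np.radians(obs.solar_zenith)
    phi_t = np.radians(terrain_relative_azimuth(obs.solar_azimuth, obs.aspect))
    return illumination_factor(alpha, theta_s, phi_t)


def select_fit_sample(cube, obs, min_sample=1000, seed=0, ndvi=None,
                      ndvi_threshold=0.05, max_sample=100_000):
    """Random (row, col) sample of vegetated valid pixels for the C fit.

    NDVI is computed on the uncorrected cube when not supplied; the ratio
    index is only weakly sensitive to terrain modulation, which is what
    makes it usable before the correction itself.
    """
    if ndvi is None:
        from .brdf import compute_ndvi  # local import; brdf does not import topo

        ndvi = compute_ndvi(cube)
    eligible = cube.valid_mask & obs.valid_mask & np.isfinite(ndvi) & (ndvi >= ndvi_threshold)
    rows, cols = np.nonzero(eligible)
    if rows.size < min_sample:
        raise DataError(
            f"only {rows.size} pixels eligible for the topographic fit "
            f"(minimum {min_sample})"
        )
    rng = np.random.default_rng(seed)
    if rows.size > max_sample:
        idx = rng.choice(rows.size, size=max_sample, replace=False)
        idx.sort()
        rows, cols = rows[idx], cols[idx]
    return rows, cols


def fit_c_factor(cube, obs, sample, b_threshold=1e-6) -> TopoFit:
    """Per-band OLS of reflectance on cos i over the pixel sample.

    ``sample`` is a (rows, cols) index pair, e.g. from
    :func:`select_fit_sample`.
    """
    rows, cols = sample
    if rows.size < 2:
        raise DataError("topographic fit needs at least 2 sample pixels")
    cos_i = _cos_i_field(obs)[rows, cols]
    if np.ptp(cos_i) == 0.0:
        raise DataError("cos i has zero variance over the fit sample")
    y = cube.values[:, rows, cols].T  # (n_sample, n_bands)
    design = np.column_stack([np.ones_like(cos_i), cos_i])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    a, b = beta[0], beta[1]
    degenerate = np.abs(b) < b_threshold
    c = np.where(degenerate, np.nan, a / np.where(degenerate, 1.0, b))
    if degenerate.any():
        log.warning("topographic fit degenerate for %d band(s); passed through",
                    int(degenerate.sum()))
    return TopoFit(a=a, b=b, c=c, degenerate=degenerate,
                   fit_sample_size=int(rows.size))


def apply_scs_c(cube, obs, fit: TopoFit):
    """Apply the SCS+C correction; returns a new cube.

    Degenerate bands pass through unchanged; pixels where |cos i + C| falls
    under the division guard are masked in the output and counted.
    """
    out = cube.copy()
    valid = cube.valid_mask & obs.valid_mask
    alpha = np.radians(obs.slope)
    theta_s = np.radians(obs.solar_zenith)
    cos_i = _cos_i_field(obs)
    scs = np.cos(alpha) * np.cos(theta_s)

    n_guarded = 0
    for band in range(cube.header.n_bands):
        if fit.degenerate[band]:
            continue
        c = fit.c[band]
        denom = cos_i + c
        bad = valid & (np.abs(denom) < DENOM_GUARD)
        if bad.any():
            n_guarded += int(bad.sum())
            out.valid_mask[bad] = False
        ok = valid & ~bad
        # ratio first: on flat terrain (cos i == scs) this is exactly 1.0
        out.values[band][ok] = cube.values[band][ok] * ((scs[ok] + c) / denom[ok])
    if n_guarded:
        log.warning("SCS+C: masked %d pixel/band cells with |cos i + C| < %g",
                    n_guarded, DENOM_GUARD)
    return out
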