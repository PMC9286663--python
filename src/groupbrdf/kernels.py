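"""Ross (volumetric) and Li (geometric) BRDF kernels.

The kernel-driven semi-empirical model expresses directional reflectance as

    rho(theta_v, theta_s, phi) = f_iso + f_geo * K_geo + f_vol * K_vol

where K_geo captures shadowing by discrete crowns (Li kernels) and K_vol the
scattering of randomly oriented facets such as leaves (Ross kernels).  Both
kernels vanish at nadir sun and nadir view, so f_iso is the modeled
nadir-sun/nadir-view reflectance.

The Li kernels operate on "primed" zenith angles rescaled by the crown
shape ratio b/r; crown relative height h/b enters the overlap term.  The
defaults b/r = 10, h/b = 2 follow common savanna/woodland usage.  All four
sparse/dense x thick/thin combinations are selectable; Li-Sparse here is the
non-reciprocal form (the cos-xi' term carries sec(theta_v') only).

All angles are radians; callers convert from degrees exactly once at module
entry (see :func:`kernel_surface`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DataError
from .solar import relative_azimuth

GEOMETRIC_KERNELS = ("li_sparse", "li_dense")
VOLUMETRIC_KERNELS = ("ross_thick", "ross_thin")


@dataclass(frozen=True)
class KernelShapeConstants:
    """Crown shape (b/r) and relative height (h/b) ratios of the Li kernels."""

    b_over_r: float = 10.0
    h_over_b: float = 2.0

    def __post_init__(self):
        if self.b_over_r <= 0 or self.h_over_b <= 0:
            raise ConfigurationError("kernel shape constants must be positive")


@dataclass(frozen=True)
class KernelChoice:
    geometric: str = "li_sparse"
    volumetric: str = "ross_thick"

    def __post_init__(self):
        if self.geometric not in GEOMETRIC_KERNELS:
            raise ConfigurationError(f"unknown geometric kernel {self.geometric!r}")
        if self.volumetric not in VOLUMETRIC_KERNELS:
            raise ConfigurationError(f"unknown volumetric kernel {self.volumetric!r}")


@dataclass
class KernelValues:
    k_geo: np.ndarray
    k_vol: np.ndarray
    valid_mask: np.ndarray | None = None


def _check_finite(*arrays):
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise DataError("non-finite angle passed to kernel computation")


def primed_angle(theta, constants: KernelShapeConstants = KernelShapeConstants()):
    """theta' = arctan((b/r) tan theta); equal-area crown rescaling."""
    theta = np.asarray(theta, dtype=float)
    _check_finite(theta)
    return np.arctan(constants.b_over_r * np.tan(theta))


def _phase_angle(theta_s, theta_v, phi):
    """cos xi = cos t_s cos t_v + sin t_s sin t_v cos phi, and xi."""
    cos_xi = (np.cos(theta_s) * np.cos(theta_v)
              + np.sin(theta_s) * np.sin(theta_v) * np.cos(phi))
    cos_xi = np.clip(cos_xi, -1.0, 1.0)
    return cos_xi, np.arccos(cos_xi)


def li_kernel(theta_s, theta_v, phi,
              choice: KernelChoice = KernelChoice(),
              constants: KernelShapeConstants = KernelShapeConstants()):
    """Li geometric kernel (sparse or dense) for radian geometry."""
    theta_s, theta_v, phi = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (theta_s, theta_v, phi)))
    _check_finite(theta_s, theta_v, phi)

    tsp = primed_angle(theta_s, constants)
    tvp = primed_angle(theta_v, constants)
    tan_sp, tan_vp = np.tan(tsp), np.tan(tvp)
    sec_sp, sec_vp = 1.0 / np.cos(tsp), 1.0 / np.cos(tvp)

    d_sq = tan_sp**2 + tan_vp**2 - 2.0 * tan_sp * tan_vp * np.cos(phi)
    d_sq = np.maximum(d_sq, 0.0)
    # Overlap of crown shadows: cos t clamped for grazing geometries.
    cos_t = (constants.h_over_b
             * np.sqrt(d_sq + (tan_sp * tan_vp * np.sin(phi)) ** 2)
             / (sec_sp + sec_vp))
    cos_t = np.clip(cos_t, -1.0, 1.0)
    t = np.arccos(cos_t)
    overlap = (t - np.sin(t) * cos_t) * (sec_sp + sec_vp) / np.pi

    cos_xi_p, _ = _phase_angle(tsp, tvp, phi)
    if choice.geometric == "li_sparse":
        k = overlap - sec_sp - sec_vp + 0.5 * (1.0 + cos_xi_p) * sec_vp
    else:  # li_dense
        k = (1.0 + cos_xi_p) * sec_vp / (sec_sp + sec_vp - overlap) - 2.0
    return k if k.ndim else float(k)


def ross_kernel(theta_s, theta_v, phi,
                choice: KernelChoice = KernelChoice()):
    """Ross volumetric kernel (thick or thin) for radian geometry."""
    theta_s, theta_v, phi = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (theta_s, theta_v, phi)))
    _check_finite(theta_s, theta_v, phi)
    cos_xi, xi = _phase_angle(theta_s, theta_v, phi)
    numer = (np.pi / 2.0 - xi) * cos_xi + np.sin(xi)
    if choice.volumetric == "ross_thick":
        k = numer / (np.cos(theta_s) + np.cos(theta_v)) - np.pi / 4.0
    else:  # ross_thin
        k = numer / (np.cos(theta_s) * np.cos(theta_v)) - np.pi / 2.0
    return k if k.ndim else float(k)


def kernel_surface(obs, choice: KernelChoice = KernelChoice(),
                   constants: KernelShapeConstants = KernelShapeConstants()) -> KernelValues:
    """Per-pixel kernel values for an observation stack (degrees in, NaN on
    masked pixels)."""
    if not obs.valid_mask.any():
        raise DataError("observation stack has no valid pixels")
    m = obs.valid_mask
    theta_s = np.radians(obs.solar_zenith[m])
    theta_v = np.radians(obs.sensor_zenith[m])
    phi = np.radians(relative_azimuth(obs.solar_azimuth[m], obs.sensor_azimuth[m]))
    k_geo = np.full(obs.shape, np.nan)
    k_vol = np.full(obs.shape, np.nan)
    k_geo[m] = li_kernel(theta_s, theta_v, phi, choice, constants)
    k_vol[m] = ross_kernel(theta_s, theta_v, phi, choice)
    return KernelValues(k_geo=k_geo, k_vol=k_vol, valid_mask=m.copy())


def kernels_at(theta_s, theta_v, phi, choice: KernelChoice = KernelChoice(),
               constants: KernelShapeConstants = KernelShapeConstants()):
    """Convenience: (K_geo, K_vol) for radian geometry arrays/scalars."""
    return (li_kernel(theta_s, theta_v, phi, choice, constants),
            ross_kernel(theta_s, theta_v, phi, choice))
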