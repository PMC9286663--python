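"""Independent scalar transcriptions used as oracles.

These are written directly from the kernel definitions using only the
``math`` module, one pixel at a time, deliberately sharing no code with the
vectorized implementation they check.
"""

import math


def primed(theta, b_over_r):
    return math.atan(b_over_r * math.tan(theta))


def li_scalar(theta_s, theta_v, phi, geometric="li_sparse",
              b_over_r=10.0, h_over_b=2.0):
    tsp = primed(theta_s, b_over_r)
    tvp = primed(theta_v, b_over_r)
    d2 = (math.tan(tsp) ** 2 + math.tan(tvp) ** 2
          - 2.0 * math.tan(tsp) * math.tan(tvp) * math.cos(phi))
    if d2 < 0.0:
        d2 = 0.0
    sec_s = 1.0 / math.cos(tsp)
    sec_v = 1.0 / math.cos(tvp)
    cos_t = (h_over_b
             * math.sqrt(d2 + (math.tan(tsp) * math.tan(tvp) * math.sin(phi)) ** 2)
             / (sec_s + sec_v))
    cos_t = max(-1.0, min(1.0, cos_t))
    t = math.acos(cos_t)
    big_o = (t - math.sin(t) * cos_t) * (sec_s + sec_v) / math.pi
    cos_xi_p = (math.cos(tsp) * math.cos(tvp)
                + math.sin(tsp) * math.sin(tvp) * math.cos(phi))
    if geometric == "li_sparse":
        return big_o - sec_s - sec_v + 0.5 * (1.0 + cos_xi_p) * sec_v
    return (1.0 + cos_xi_p) * sec_v / (sec_s + sec_v - big_o) - 2.0


def ross_scalar(theta_s, theta_v, phi, volumetric="ross_thick"):
    cos_xi = (math.cos(theta_s) * math.cos(theta_v)
              + math.sin(theta_s) * math.sin(theta_v) * math.cos(phi))
    cos_xi = max(-1.0, min(1.0, cos_xi))
    xi = math.acos(cos_xi)
    numer = (math.pi / 2.0 - xi) * cos_xi + math.sin(xi)
    if volumetric == "ross_thick":
        return numer / (math.cos(theta_s) + math.cos(theta_v)) - math.pi / 4.0
    return numer / (math.cos(theta_s) * math.cos(theta_v)) - math.pi / 2.0


def illumination_scalar(alpha, theta_s, phi_t):
    return (math.cos(alpha) * math.cos(theta_s)
            + math.sin(alpha) * math.sin(theta_s) * math.cos(phi_t))
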