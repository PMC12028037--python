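"""Geodesic distances on the WGS84 reference ellipsoid.

Solves the inverse geodesic problem with Vincenty's iterative formulae
(sub-millimetre agreement with high-precision references for non-antipodal
pairs). Nearly antipodal pairs, where Vincenty's lambda iteration can fail
to converge, fall back to a damped iteration and are flagged via a warning.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

# WGS84 defining parameters
_A = 6378137.0                # semi-major axis, m
_F = 1.0 / 298.257223563      # flattening
_B = _A * (1.0 - _F)          # semi-minor axis, m


def geodesic_distance(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Distance in meters between two (latitude, longitude) points in degrees."""
    if (lat1, lon1) == (lat2, lon2):
        return 0.0
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    L = math.radians(lon2 - lon1)
    U1 = math.atan((1 - _F) * math.tan(phi1))
    U2 = math.atan((1 - _F) * math.tan(phi2))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)

    lam = L
    converged = False
    damping = 1.0
    for attempt in range(2):
        for _ in range(200):
            sinlam, coslam = math.sin(lam), math.cos(lam)
            sin_sigma = math.hypot(cosU2 * sinlam, cosU1 * sinU2 - sinU1 * cosU2 * coslam)
            if sin_sigma == 0.0:
                return 0.0  # coincident points
            cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * coslam
            sigma = math.atan2(sin_sigma, cos_sigma)
            sin_alpha = cosU1 * cosU2 * sinlam / sin_sigma
            cos2_alpha = 1.0 - sin_alpha * sin_alpha
            if cos2_alpha == 0.0:
                cos_2sigma_m = 0.0  # equatorial line
            else:
                cos_2sigma_m = cos_sigma - 2.0 * sinU1 * sinU2 / cos2_alpha
            C = _F / 16.0 * cos2_alpha * (4.0 + _F * (4.0 - 3.0 * cos2_alpha))
            lam_new = L + (1.0 - C) * _F * sin_alpha * (
                sigma + C * sin_sigma * (cos_2sigma_m + C * cos_sigma * (-1.0 + 2.0 * cos_2sigma_m ** 2))
            )
            lam_new = lam + damping * (lam_new - lam)
            if abs(lam_new - lam) < 1e-13:
                lam = lam_new
                converged = True
                break
            lam = lam_new
        if converged:
            break
        # nearly antipodal: damp the fixed-point iteration and retry
        damping = 0.5
        lam = L
    if not converged:
        warnings.warn("Vincenty iteration did not fully converge (nearly antipodal pair); "
                      "result from damped iteration", RuntimeWarning)

    u2 = cos2_alpha * (_A * _A - _B * _B) / (_B * _B)
    A_coef = 1.0 + u2 / 16384.0 * (4096.0 + u2 * (-768.0 + u2 * (320.0 - 175.0 * u2)))
    B_coef = u2 / 1024.0 * (256.0 + u2 * (-128.0 + u2 * (74.0 - 47.0 * u2)))
    delta_sigma = B_coef * sin_sigma * (
        cos_2sigma_m + B_coef / 4.0 * (
            cos_sigma * (-1.0 + 2.0 * cos_2sigma_m ** 2)
            - B_coef / 6.0 * cos_2sigma_m * (-3.0 + 4.0 * sin_sigma ** 2) * (-3.0 + 4.0 * cos_2sigma_m ** 2)
        )
    )
    return _B * A_coef * (sigma - delta_sigma)


def geodesic_matrix(latitudes, longitudes) -> np.ndarray:
    """Symmetric pairwise geodesic distance matrix in meters."""
    lat = np.asarray(latitudes, dtype=float)
    lon = np.asarray(longitudes, dtype=float)
    n = lat.size
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = geodesic_distance(lat[i], lon[i], lat[j], lon[j])
    return out
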