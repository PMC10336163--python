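"""Circular-statistics primitives shared across the package.

All public functions work in degrees, matching the camera's head-direction
convention, and return degrees. Angles are wrapped to [0, 360).
"""

from __future__ import annotations

import numpy as np
from scipy.special import i0, i1


def wrap_deg(a):
    """Wrap angle(s) to [0, 360)."""
    r = np.mod(a, 360.0)
    # np.mod(-eps, 360) rounds to 360.0 for tiny eps; keep the half-open range
    return np.where(r >= 360.0, 0.0, r) if np.ndim(r) else (0.0 if r >= 360.0 else r)


def wrap_diff_deg(a):
    """Wrap angular difference(s) to the shortest signed arc (-180, 180]."""
    return 180.0 - np.mod(180.0 - np.asarray(a, dtype=float), 360.0)


def circ_diff_deg(a, b):
    """Shortest signed arc from b to a, in (-180, 180]."""
    return wrap_diff_deg(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def mean_vector(angles_deg, weights=None):
    """Mean resultant vector of angular data.

    Parameters
    ----------
    angles_deg : array-like
        Angles in degrees.
    weights : array-like, optional
        Non-negative weights (e.g. per-bin firing rates).

    Returns
    -------
    R : float
        Mean resultant length in [0, 1].
    mean_deg : float
        Circular mean direction in [0, 360). NaN when R is 0.
    """
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    if weights is None:
        w = np.ones_like(a)
    else:
        w = np.asarray(weights, dtype=float)
    tot = w.sum()
    if tot <= 0:
        return 0.0, np.nan
    z = np.sum(w * np.exp(1j * a)) / tot
    R = float(np.abs(z))
    mean_deg = float(wrap_deg(np.rad2deg(np.angle(z)))) if R > 0 else np.nan
    return R, mean_deg


def circ_sd_deg(R):
    """Circular standard deviation sqrt(-2 ln R), in degrees."""
    R = float(R)
    if R <= 0:
        return np.inf
    if R >= 1:
        return 0.0
    return float(np.rad2deg(np.sqrt(-2.0 * np.log(R))))


def kappa_from_R(R):
    """Maximum-likelihood von Mises concentration from a resultant length.

    Standard series/rational approximations (Fisher 1993).
    """
    R = float(min(max(R, 0.0), 1.0 - 1e-12))
    if R < 0.53:
        return 2 * R + R**3 + 5 * R**5 / 6
    if R < 0.85:
        return -0.4 + 1.39 * R + 0.43 / (1 - R)
    denom = R**3 - 4 * R**2 + 3 * R
    return 1.0 / denom if denom > 1e-9 else 1e9


def bessel_ratio(kappa):
    """I1(kappa)/I0(kappa): expected resultant length of a von Mises sample."""
    return float(i1(kappa) / i0(kappa))


def rayleigh_test(angles_deg, weights=None):
    """Rayleigh test of circular uniformity.

    Returns (R, z, p) with z = n R^2 and the standard large-n p
    approximation (Zar 1999).
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size < 2:
        raise ValueError("rayleigh test needs at least 2 angles")
    R, _ = mean_vector(a, weights)
    n = a.size if weights is None else float(np.sum(weights))
    z = n * R**2
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - (n * R) ** 2)) - (1 + 2 * n))
    return float(R), float(z), float(min(max(p, 0.0), 1.0))


def taylor_bandwidth(angles_deg):
    """Plug-in concentration for von Mises kernel density estimation.

    Taylor (2008) rule: nu = (3 n k^2 I2(2k) / (4 sqrt(pi) I0(k)^2))^(2/5)
    where k is the ML concentration of the sample. Returns the kernel
    concentration nu (dimensionless, larger = narrower kernel).
    """
    from scipy.special import i0e, ive

    a = np.asarray(angles_deg, dtype=float)
    n = a.size
    R, _ = mean_vector(a)
    k = kappa_from_R(R)
    k = max(k, 1e-3)
    # exponentially scaled Bessels: iv(2, 2k)/i0(k)^2 = ive(2, 2k)/i0e(k)^2,
    # so the e^{2k} factors cancel and large k cannot overflow
    ratio = ive(2, 2 * k) / i0e(k) ** 2
    nu = (3.0 * n * k**2 * ratio / (4.0 * np.sqrt(np.pi))) ** 0.4
    if not np.isfinite(nu):
        nu = 1e4
    # a kernel SD below ~0.5 degree is finer than any 1-degree grid
    return float(min(max(nu, 1e-3), 1e4))


def vonmises_kde(angles_deg, grid_deg=None, bandwidth=None):
    """Circular kernel density estimate with a von Mises kernel.

    Parameters
    ----------
    angles_deg : array-like
    grid_deg : array-like, optional
        Evaluation grid; defaults to 1-degree resolution over [0, 360).
    bandwidth : float, optional
        Kernel concentration; defaults to the Taylor plug-in value.

    Returns
    -------
    grid_deg, density : ndarray
        density integrates to 1 over the circle (radian measure).
    """
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    if grid_deg is None:
        grid_deg = np.arange(0.0, 360.0, 1.0)
    g = np.deg2rad(np.asarray(grid_deg, dtype=float))
    if bandwidth is None:
        bandwidth = taylor_bandwidth(angles_deg)
    nu = float(bandwidth)
    # kernel exp(nu cos(d))/(2 pi I0(nu)) evaluated as
    # exp(nu (cos(d) - 1))/(2 pi i0e(nu)) so large nu cannot overflow
    from scipy.special import i0e
    d = np.exp(nu * (np.cos(g[:, None] - a[None, :]) - 1.0)).sum(axis=1)
    d /= a.size * 2 * np.pi * i0e(nu)
    return np.asarray(grid_deg, dtype=float), d


def interp_angle_deg(t, tp, hd_deg):
    """Interpolate an angular time series at times t (circular linear interp).

    Works on the unwrapped phase so interpolation takes the short way
    around between consecutive samples.
    """
    unwrapped = np.rad2deg(np.unwrap(np.deg2rad(np.asarray(hd_deg, dtype=float))))
    return wrap_deg(np.interp(t, tp, unwrapped))
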