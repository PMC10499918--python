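"""Independent analytic / numeric scattering references.

Two families of oracle live here, both independent of the stacked-cylinder
scattering engine:

* the exact partial-wave (modal) series for a fluid sphere in a fluid — the
  classical benchmark for any approximate backscatter model, valid at all ka;
* a Kirchhoff-Helmholtz surface-integral quadrature for a sound-soft (gas)
  prolate spheroid at dorsal incidence.  This is a *synthetic stand-in* for an
  externally computed full-wave (FEM/BEM) spectrum: it solves the same
  physical-optics boundary integral a full-wave code discretizes, by direct
  2-D quadrature over the illuminated surface, but it remains a high-frequency
  approximation and is labelled accordingly wherever it is used.

Scattering lengths are in metres, sigma_bs = |L|^2 in m^2 and
TS = 10 log10(sigma_bs) in dB re 1 m^2.
"""

from __future__ import annotations

import math
from typing import Tuple

import numpy as np
from scipy.special import spherical_jn, spherical_yn

from .exceptions import ConvergenceError, DomainError

__all__ = [
    "fluid_sphere_scattering_length",
    "sphere_modal_ts",
    "rayleigh_fluid_sphere_ts",
    "kirchhoff_spheroid_scattering_length",
    "kirchhoff_spheroid_spectrum",
]


def fluid_sphere_scattering_length(
    a: float,
    sphere: Tuple[float, float],
    ambient: Tuple[float, float],
    f: float,
    rtol: float = 1e-6,
) -> complex:
    """Exact backscattering length of a fluid sphere (partial-wave series).

    Parameters
    ----------
    a : float
        Sphere radius (m).
    sphere, ambient : (c, rho)
        Sound speed (m/s) and density (kg/m^3) of sphere and surrounding fluid.
    f : float
        Frequency (Hz).

    Returns
    -------
    complex
        Far-field backscattering length L (m); sigma_bs = |L|^2.

    Notes
    -----
    Continuity of pressure and normal velocity at r = a gives, for each mode n,

        A_n = -[j_n'(x) j_n(x1) - (1/(g h)) j_n(x) j_n'(x1)]
             / [h_n'(x) j_n(x1) - (1/(g h)) h_n(x) j_n'(x1)]

    with x = k a in the ambient fluid, x1 = x/h, h = c1/c, g = rho1/rho, and
    L = (1/(i k)) sum (2n+1) (-1)^n A_n.  The series is truncated when the
    partial sum is converged to ``rtol``; at least ka + 10 modes are summed.
    """
    if a <= 0:
        raise DomainError("sphere radius must be > 0")
    if f <= 0:
        raise DomainError("frequency must be > 0")
    c1, rho1 = sphere
    c, rho = ambient
    if min(c1, rho1, c, rho) <= 0:
        raise DomainError("material parameters must be > 0")

    k = 2.0 * math.pi * f / c
    x = k * a
    h = c1 / c
    g = rho1 / rho
    x1 = x / h
    gh_inv = 1.0 / (g * h)

    n_min = int(math.ceil(x)) + 10
    n_max = max(4 * n_min, 200)
    total = 0.0 + 0.0j
    converged = False
    for n in range(n_max + 1):
        jn_x = spherical_jn(n, x)
        djn_x = spherical_jn(n, x, derivative=True)
        yn_x = spherical_yn(n, x)
        dyn_x = spherical_yn(n, x, derivative=True)
        hn_x = jn_x + 1j * yn_x
        dhn_x = djn_x + 1j * dyn_x
        jn_x1 = spherical_jn(n, x1)
        djn_x1 = spherical_jn(n, x1, derivative=True)

        num = djn_x * jn_x1 - gh_inv * jn_x * djn_x1
        den = dhn_x * jn_x1 - gh_inv * hn_x * djn_x1
        an = -num / den
        term = (2 * n + 1) * ((-1) ** n) * an
        total += term
        if n >= n_min and abs(term) <= rtol * max(abs(total), 1e-300):
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"fluid-sphere modal series not converged after {n_max + 1} modes "
            f"(ka={x:.3g})"
        )
    return total / (1j * k)


def sphere_modal_ts(
    a: float,
    sphere: Tuple[float, float],
    ambient: Tuple[float, float],
    f: float,
    rtol: float = 1e-6,
) -> float:
    """Exact TS (dB re 1 m^2) of a fluid sphere from the modal series."""
    L = fluid_sphere_scattering_length(a, sphere, ambient, f, rtol=rtol)
    sigma_bs = abs(L) ** 2
    if sigma_bs == 0.0:
        return -math.inf
    return 10.0 * math.log10(sigma_bs)


def rayleigh_fluid_sphere_ts(
    a: float, sphere: Tuple[float, float], ambient: Tuple[float, float], f: float
) -> float:
    """Rayleigh-limit (ka << 1) backscatter TS of a weak fluid sphere.

    Closed form L = (k^2 a^3 / 3)(gamma_kappa - gamma_rho) with the
    compressibility and density contrast terms
    gamma_kappa = (1 - g h^2)/(g h^2) and gamma_rho = 3(g - 1)/(2g + 1).
    """
    c1, rho1 = sphere
    c, rho = ambient
    k = 2.0 * math.pi * f / c
    g = rho1 / rho
    h = c1 / c
    gamma_kappa = (1.0 - g * h * h) / (g * h * h)
    gamma_rho = 3.0 * (g - 1.0) / (2.0 * g + 1.0)
    L = (k * k * a**3 / 3.0) * (gamma_kappa - gamma_rho)
    return 10.0 * math.log10(L * L)


def kirchhoff_spheroid_scattering_length(
    semi_major: float,
    semi_minor: float,
    f: float,
    c_w: float = 1509.0,
    n_quad: int = 400,
) -> complex:
    """Physical-optics backscattering length of a sound-soft prolate spheroid.

    Dorsal (broadside) incidence on a spheroid with axis of revolution
    perpendicular to the incident direction; semi-axes in metres.  Evaluates
    the Kirchhoff (physical-optics) boundary integral for a pressure-release
    surface,

        L(f) = (k / 2 pi i) * integral over the illuminated projection of
               exp(2 i k zeta(x, y)) dx dy,

    with zeta the height of the upper surface, by midpoint quadrature on the
    projected ellipse.  High-frequency approximation: exact in the specular
    limit (|L| -> sqrt(R1 R2)/2) but without the low-ka corrections a
    full-wave solution carries.

    .. note:: synthetic stand-in — used as the built-in reference spectrum
       when no externally computed full-wave (FEM/BEM) spectrum is supplied.
    """
    if semi_major <= 0 or semi_minor <= 0:
        raise DomainError("spheroid semi-axes must be > 0")
    if f <= 0:
        raise DomainError("frequency must be > 0")
    k = 2.0 * math.pi * f / c_w
    # projected outline: ellipse with semi-axes (semi_major, semi_minor)
    x = (np.arange(n_quad) + 0.5) / n_quad * 2.0 - 1.0  # in (-1, 1)
    y = x.copy()
    dx = 2.0 * semi_major / n_quad
    dy = 2.0 * semi_minor / n_quad
    X, Y = np.meshgrid(x * semi_major, y * semi_minor, indexing="ij")
    r2 = (X / semi_major) ** 2 + (Y / semi_minor) ** 2
    inside = r2 < 1.0
    zeta = np.zeros_like(X)
    zeta[inside] = semi_minor * np.sqrt(1.0 - r2[inside])
    integrand = np.where(inside, np.exp(2j * k * zeta), 0.0)
    integral = integrand.sum() * dx * dy
    return k / (2.0j * math.pi) * integral


def kirchhoff_spheroid_spectrum(
    semi_major: float,
    semi_minor: float,
    f_hz: np.ndarray,
    c_w: float = 1509.0,
    n_quad: int = 400,
) -> np.ndarray:
    """TS(f) of the sound-soft spheroid from the Kirchhoff surface integral.

    Synthetic stand-in reference spectrum (see
    :func:`kirchhoff_spheroid_scattering_length`).
    """
    f_hz = np.asarray(f_hz, dtype=float)
    ts = np.empty_like(f_hz)
    for i, f in enumerate(f_hz):
        L = kirchhoff_spheroid_scattering_length(
            semi_major, semi_minor, f, c_w=c_w, n_quad=n_quad
        )
        ts[i] = 10.0 * math.log10(abs(L) ** 2)
    return ts
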