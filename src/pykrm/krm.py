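"""Kirchhoff Ray Mode (KRM) backscatter engine.

The fish is discretized into short cylinders between consecutive digitized
stations.  The backscattering length is the coherent sum of

* a soft-boundary term over the gas-filled swimbladder cylinders, scaled by
  the body->gas reflection coefficient and the water->body transmission
  product, with the published empirical low-ka amplitude and phase
  corrections; and
* a fluid-boundary term over the fish-body cylinders: the front-interface
  echo minus the internally transmitted back-interface echo, whose phase is
  advanced by twice the body wavenumber times the local body thickness.

Cylinders are formed at station midpoints, so the tapering terminal elements
carry the shrinking radii of the digitized outline.  Incidence angles are
restricted to 65-115 degrees (dorsal broadside = 90 degrees), the range in
which the ray approximation holds; the geometry is rotated by (theta - 90)
degrees about its centroid before acoustic depths are computed.

Amplitude conventions: scattering length L in metres, sigma_bs = |L|^2 (m^2),
TS = 10 log10(sigma_bs) dB re 1 m^2 (equivalently 10 log10(sigma/4pi) with
sigma = 4 pi sigma_bs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .exceptions import (
    DeflatedSpecimenError,
    DomainError,
    ValidityRangeError,
)
from .shapes import FishModel, MaterialSet

__all__ = [
    "THETA_MIN",
    "THETA_MAX",
    "reflection_coefficient",
    "KRM",
    "BackscatterGrid",
    "krm_scattering_length",
    "krm_grid",
    "slice_sensitivity",
    "SliceSensitivityResult",
    "spectrum_max_diff",
    "SpectrumDiff",
    "lambda_over_10_mm",
]

THETA_MIN = 65.0
THETA_MAX = 115.0

#: empirical low-ka corrections of the soft-cylinder ray solution
_A_SB_CONST = 0.083
_PSI_P_SCALE = 40.0
_PSI_P_OFFSET = 1.05
_PSI_B_CONST = 0.4

_MM = 1e-3


def reflection_coefficient(rho1: float, c1: float, rho2: float, c2: float) -> float:
    """Plane-wave pressure reflection coefficient from medium 1 onto medium 2.

    R = (Z2 - Z1)/(Z2 + Z1) with acoustic impedance Z = rho c; antisymmetric
    under swapping the media and bounded in (-1, 1) for positive impedances.
    """
    if min(rho1, c1, rho2, c2) <= 0:
        raise DomainError("densities and sound speeds must be > 0")
    z1 = rho1 * c1
    z2 = rho2 * c2
    return (z2 - z1) / (z2 + z1)


def lambda_over_10_mm(c_w: float = 1509.0, f_ref_hz: float = 200e3) -> float:
    """Slice thickness lambda/10 (mm) at the reference frequency (200 kHz)."""
    return c_w / f_ref_hz / 10.0 * 1e3


def _check_theta(theta: float) -> None:
    if not (THETA_MIN <= theta <= THETA_MAX):
        raise ValidityRangeError(
            f"incidence angle {theta} deg outside KRM validity range "
            f"[{THETA_MIN}, {THETA_MAX}] deg"
        )


def _rotate(u: np.ndarray, z: np.ndarray, alpha: float, u0: float, z0: float):
    """Rotate points by alpha (rad) about (u0, z0); returns rotated z only
    where used alongside unrotated axial slice lengths."""
    ca, sa = math.cos(alpha), math.sin(alpha)
    du, dz = u - u0, z - z0
    return u0 + ca * du - sa * dz, z0 + sa * du + ca * dz


def _midpoints(x: np.ndarray) -> np.ndarray:
    return 0.5 * (x[:-1] + x[1:])


@dataclass(frozen=True)
class BackscatterGrid:
    """Complex scattering length and TS over frequency x tilt.

    ``scattering_length`` has shape (n_freq, n_theta); ``sigma_bs`` and ``ts``
    are pure element-wise conversions of it.
    """

    f_hz: np.ndarray
    theta_deg: np.ndarray
    scattering_length: np.ndarray
    c_w: float
    c_fb: float

    @property
    def sigma_bs(self) -> np.ndarray:
        """Backscattering cross-section |L|^2 (m^2)."""
        return np.abs(self.scattering_length) ** 2

    @property
    def ts(self) -> np.ndarray:
        """Target strength 10 log10(sigma_bs) (dB re 1 m^2)."""
        with np.errstate(divide="ignore"):
            return 10.0 * np.log10(self.sigma_bs)

    @property
    def k_w(self) -> np.ndarray:
        return 2.0 * np.pi * self.f_hz / self.c_w

    @property
    def k_fb(self) -> np.ndarray:
        return 2.0 * np.pi * self.f_hz / self.c_fb

    def ts_at(self, f_hz: float, theta_deg: float) -> float:
        i = int(np.argmin(np.abs(self.f_hz - f_hz)))
        j = int(np.argmin(np.abs(self.theta_deg - theta_deg)))
        return float(self.ts[i, j])

    def sigma_at_theta(self, theta_deg: float) -> np.ndarray:
        j = int(np.argmin(np.abs(self.theta_deg - theta_deg)))
        return self.sigma_bs[:, j]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with columns f_hz, theta_deg, ts_db, sigma_bs_m2."""
        F, T = np.meshgrid(self.f_hz, self.theta_deg, indexing="ij")
        return pd.DataFrame(
            {
                "f_hz": F.ravel(),
                "theta_deg": T.ravel(),
                "ts_db": self.ts.ravel(),
                "sigma_bs_m2": self.sigma_bs.ravel(),
            }
        )


class KRM:
    """KRM forward model for one specimen.

    Parameters
    ----------
    fish : FishModel
        Digitized specimen; the swimbladder must be inflated for any
        computation involving the soft term.
    materials : MaterialSet
        Water / fish body / swimbladder acoustic properties.
    du_mm : float
        Working slice thickness (mm); profiles are resampled to this spacing
        before the cylinder sum.  1 mm is the recommended operational value.
    """

    def __init__(
        self,
        fish: FishModel,
        materials: MaterialSet = MaterialSet(),
        du_mm: float = 1.0,
    ):
        if not du_mm > 0:
            raise DomainError("slice thickness must be > 0")
        self.fish = fish.resampled(du_mm)
        self.materials = materials
        self.du_mm = du_mm
        m = materials
        # exterior of the bladder: fish flesh when a body is modelled, else water
        self._c_ext = m.c_fb if self.fish.body is not None else m.c_w
        self._rho_ext = m.rho_fb if self.fish.body is not None else m.rho_w
        self.r_wb = (
            reflection_coefficient(m.rho_w, m.c_w, m.rho_fb, m.c_fb)
            if self.fish.body is not None
            else 0.0
        )
        self.r_bc = reflection_coefficient(
            self._rho_ext, self._c_ext, m.rho_sb, m.c_sb
        )

    # -- geometry ---------------------------------------------------------

    def _centroid(self) -> Tuple[float, float]:
        ref = self.fish.body if self.fish.body is not None else self.fish.bladder
        u0 = 0.5 * (ref.u[0] + ref.u[-1])
        z0 = float(np.mean(ref.midline()))
        return u0, z0

    def _soft_cylinders(self, theta: float):
        """Rotated swimbladder cylinders: (a_m, path_w_m, path_b_m, du_m)."""
        b = self.fish.bladder
        alpha = math.radians(theta - 90.0)
        u0, z0 = self._centroid()

        u_mid = _midpoints(b.u)
        zU_mid = _midpoints(b.z_upper)
        a_mid = _midpoints(b.w) / 2.0
        du = np.diff(b.u)
        _, zU_rot = _rotate(u_mid, zU_mid, alpha, u0, z0)

        if self.fish.body is not None:
            body = self.fish.body
            zbU_mid = np.interp(u_mid, body.u, body.z_upper)
            _, zbU_rot = _rotate(u_mid, zbU_mid, alpha, u0, z0)
            path_w = -zbU_rot           # water path above the body surface
            path_b = np.maximum(zbU_rot - zU_rot, 0.0)
        else:
            path_w = -zU_rot
            path_b = np.zeros_like(zU_rot)
        return a_mid * _MM, path_w * _MM, path_b * _MM, du * _MM

    def _fluid_cylinders(self, theta: float):
        """Rotated body cylinders: (a_m, depth_front_m, thickness_m, du_m)."""
        body = self.fish.body
        alpha = math.radians(theta - 90.0)
        u0, z0 = self._centroid()
        u_mid = _midpoints(body.u)
        zU_mid = _midpoints(body.z_upper)
        zL_mid = _midpoints(body.z_lower)
        a_mid = _midpoints(body.w) / 2.0
        du = np.diff(body.u)
        _, zU_rot = _rotate(u_mid, zU_mid, alpha, u0, z0)
        _, zL_rot = _rotate(u_mid, zL_mid, alpha, u0, z0)
        return (
            a_mid * _MM,
            -zU_rot * _MM,
            np.maximum(zU_rot - zL_rot, 0.0) * _MM,
            du * _MM,
        )

    # -- acoustics --------------------------------------------------------

    def soft_scattering_length(
        self, f_hz: np.ndarray, theta_deg: float
    ) -> np.ndarray:
        """Soft (gas-filled swimbladder) term of the coherent sum, per frequency."""
        _check_theta(theta_deg)
        if self.fish.bladder is None:
            raise DeflatedSpecimenError("deflated specimen: no swimbladder term")
        f = np.atleast_1d(np.asarray(f_hz, dtype=float))
        if np.any(f <= 0):
            raise DomainError("frequencies must be > 0")
        m = self.materials
        k_w = 2.0 * np.pi * f / m.c_w
        k_b = 2.0 * np.pi * f / self._c_ext
        sin_t = math.sin(math.radians(theta_deg))

        a, path_w, path_b, du = self._soft_cylinders(theta_deg)
        ka = k_b[:, None] * a[None, :]
        A_sb = ka / (ka + _A_SB_CONST)
        psi_p = ka / (_PSI_P_SCALE + ka) - _PSI_P_OFFSET
        phase = (
            2.0 * k_w[:, None] * path_w[None, :]
            + 2.0 * k_b[:, None] * path_b[None, :]
            + psi_p
        )
        amp = A_sb * np.sqrt((ka + 1.0) * sin_t) * du[None, :]
        coeff = -1j * self.r_bc * (1.0 - self.r_wb**2) / (2.0 * math.sqrt(math.pi))
        return coeff * np.sum(amp * np.exp(-1j * phase), axis=1)

    def fluid_scattering_length(
        self, f_hz: np.ndarray, theta_deg: float
    ) -> np.ndarray:
        """Fluid (fish body) term of the coherent sum, per frequency."""
        _check_theta(theta_deg)
        if self.fish.body is None:
            return np.zeros(np.atleast_1d(np.asarray(f_hz)).shape, dtype=complex)
        f = np.atleast_1d(np.asarray(f_hz, dtype=float))
        if np.any(f <= 0):
            raise DomainError("frequencies must be > 0")
        m = self.materials
        k_w = 2.0 * np.pi * f / m.c_w
        k_fb = 2.0 * np.pi * f / m.c_fb
        sin_t = math.sin(math.radians(theta_deg))

        a, v_front, h, du = self._fluid_cylinders(theta_deg)
        ka_w = k_w[:, None] * a[None, :]
        kb_half = k_fb[:, None] * (h[None, :] / 2.0)
        psi_b = -math.pi / 2.0 * kb_half / (kb_half + _PSI_B_CONST)
        front = np.exp(-2j * k_w[:, None] * v_front[None, :])
        back = (1.0 - self.r_wb**2) * np.exp(
            -1j
            * (
                2.0 * k_w[:, None] * v_front[None, :]
                + 2.0 * k_fb[:, None] * h[None, :]
                - psi_b
            )
        )
        amp = np.sqrt(ka_w * sin_t) * du[None, :]
        coeff = -1j * self.r_wb / (2.0 * math.sqrt(math.pi))
        return coeff * np.sum(amp * (front - back), axis=1)

    def scattering_length(
        self, f_hz, theta_deg: float, part: str = "whole"
    ) -> np.ndarray:
        """Coherent backscattering length L(f) (m) at one incidence angle.

        ``part`` selects the swimbladder term, the body term, or their
        coherent (complex) sum.
        """
        if part not in ("whole", "bladder", "body"):
            raise DomainError(f"unknown part {part!r}")
        if part == "bladder":
            return self.soft_scattering_length(f_hz, theta_deg)
        if part == "body":
            return self.fluid_scattering_length(f_hz, theta_deg)
        if self.fish.bladder is None:
            raise DeflatedSpecimenError(
                "deflated specimen excluded from whole-fish computation"
            )
        soft = self.soft_scattering_length(f_hz, theta_deg)
        if self.fish.body is None:
            return soft
        return soft + self.fluid_scattering_length(f_hz, theta_deg)

    def run(
        self,
        f_hz: Sequence[float],
        theta_deg: Sequence[float],
        part: str = "whole",
    ) -> BackscatterGrid:
        """Populate a frequency x tilt backscatter grid."""
        f = np.atleast_1d(np.asarray(f_hz, dtype=float))
        th = np.atleast_1d(np.asarray(theta_deg, dtype=float))
        L = np.empty((f.size, th.size), dtype=complex)
        for j, t in enumerate(th):
            L[:, j] = self.scattering_length(f, float(t), part=part)
        m = self.materials
        return BackscatterGrid(
            f_hz=f, theta_deg=th, scattering_length=L, c_w=m.c_w, c_fb=m.c_fb
        )

    def ts(self, f_hz, theta_deg: float, part: str = "whole") -> np.ndarray:
        """TS(f) (dB re 1 m^2) at one incidence angle."""
        L = self.scattering_length(f_hz, theta_deg, part=part)
        with np.errstate(divide="ignore"):
            return 10.0 * np.log10(np.abs(L) ** 2)


# -- functional wrappers ---------------------------------------------------


def krm_scattering_length(
    fish: FishModel,
    materials: MaterialSet,
    f_hz: float,
    theta_deg: float,
    du_mm: float = 1.0,
    part: str = "whole",
) -> complex:
    """Backscattering length (m) of one specimen at one (f, theta)."""
    out = KRM(fish, materials, du_mm=du_mm).scattering_length(
        f_hz, theta_deg, part=part
    )
    return complex(out[0])


def krm_grid(
    fish: FishModel,
    materials: MaterialSet,
    f_hz: Sequence[float],
    theta_deg: Sequence[float],
    du_mm: float = 1.0,
    part: str = "whole",
) -> BackscatterGrid:
    """Backscatter grid of one specimen over frequency x tilt."""
    return KRM(fish, materials, du_mm=du_mm).run(f_hz, theta_deg, part=part)


# -- slice-thickness sensitivity ------------------------------------------


@dataclass(frozen=True)
class SliceSensitivityResult:
    """TS(f) curves per slice thickness plus pairwise band-max |dTS|."""

    f_hz: np.ndarray
    thicknesses_mm: Tuple[float, ...]
    labels: Tuple[str, ...]
    ts_curves: np.ndarray  # shape (n_thickness, n_freq)
    pairwise_max_dts: pd.DataFrame

    def curve(self, label: str) -> np.ndarray:
        return self.ts_curves[self.labels.index(label)]

    def max_dts(self, label_a: str, label_b: str) -> float:
        d = self.pairwise_max_dts
        row = d[
            ((d.thickness_a == label_a) & (d.thickness_b == label_b))
            | ((d.thickness_a == label_b) & (d.thickness_b == label_a))
        ]
        return float(row.max_abs_dts_db.iloc[0])


def slice_sensitivity(
    fish: FishModel,
    materials: MaterialSet,
    thicknesses: Sequence[Union[float, str]],
    f_hz: Sequence[float],
    theta_deg: float = 90.0,
    part: str = "whole",
) -> SliceSensitivityResult:
    """Compare KRM TS spectra computed at coarse and refined slice thickness.

    ``thicknesses`` entries are millimetres, or the string ``"lambda/10"``
    for one tenth of the water wavelength at the 200 kHz reference frequency.
    """
    if len(thicknesses) < 2:
        raise DomainError("need at least two slice thicknesses to compare")
    f = np.atleast_1d(np.asarray(f_hz, dtype=float))
    labels, du_values = [], []
    for t in thicknesses:
        if isinstance(t, str):
            if t.replace(" ", "") not in ("lambda/10", "l/10"):
                raise DomainError(f"unknown thickness spec {t!r}")
            du_values.append(lambda_over_10_mm(materials.c_w))
            labels.append("lambda/10")
        else:
            if not t > 0:
                raise DomainError("slice thickness must be > 0")
            du_values.append(float(t))
            labels.append(f"{float(t):g} mm")

    curves = np.vstack(
        [
            KRM(fish, materials, du_mm=du).ts(f, theta_deg, part=part)
            for du in du_values
        ]
    )
    rows = []
    for i in range(len(du_values)):
        for j in range(i + 1, len(du_values)):
            rows.append(
                {
                    "thickness_a": labels[i],
                    "thickness_b": labels[j],
                    "max_abs_dts_db": float(np.max(np.abs(curves[i] - curves[j]))),
                }
            )
    return SliceSensitivityResult(
        f_hz=f,
        thicknesses_mm=tuple(du_values),
        labels=tuple(labels),
        ts_curves=curves,
        pairwise_max_dts=pd.DataFrame(rows),
    )


# -- spectrum comparison ---------------------------------------------------


@dataclass(frozen=True)
class SpectrumDiff:
    """Band-restricted TS difference between two spectra."""

    band_hz: Tuple[float, float]
    max_abs_dts_db: float
    table: pd.DataFrame  # columns f_hz, ts_a_db, ts_b_db, dts_db


def spectrum_max_diff(
    spectrum_a: pd.DataFrame,
    spectrum_b: pd.DataFrame,
    band_hz: Tuple[float, float],
) -> SpectrumDiff:
    """Maximum absolute TS difference between two spectra over a band.

    Spectra are tables with columns ``f_hz`` and ``ts_db``; the coarser one is
    interpolated linearly in TS onto the finer grid restricted to the band.
    """
    lo, hi = band_hz
    if not hi > lo:
        raise DomainError("band upper edge must exceed lower edge")
    fa = np.asarray(spectrum_a["f_hz"], dtype=float)
    ta = np.asarray(spectrum_a["ts_db"], dtype=float)
    fb = np.asarray(spectrum_b["f_hz"], dtype=float)
    tb = np.asarray(spectrum_b["ts_db"], dtype=float)
    for f, name in ((fa, "a"), (fb, "b")):
        if f.min() > lo or f.max() < hi:
            raise DomainError(
                f"spectrum {name} does not cover the band "
                f"[{lo:g}, {hi:g}] Hz (covers [{f.min():g}, {f.max():g}])"
            )
    # finer = more nodes inside the band
    in_a = (fa >= lo) & (fa <= hi)
    in_b = (fb >= lo) & (fb <= hi)
    if in_a.sum() >= in_b.sum():
        f_ref, t_ref = fa[in_a], ta[in_a]
        t_other = np.interp(f_ref, fb, tb)
        ts_a, ts_b = t_ref, t_other
    else:
        f_ref, t_ref = fb[in_b], tb[in_b]
        t_other = np.interp(f_ref, fa, ta)
        ts_a, ts_b = t_other, t_ref
    dts = ts_a - ts_b
    table = pd.DataFrame(
        {"f_hz": f_ref, "ts_a_db": ts_a, "ts_b_db": ts_b, "dts_db": dts}
    )
    return SpectrumDiff(
        band_hz=(lo, hi),
        max_abs_dts_db=float(np.max(np.abs(dts))),
        table=table,
    )
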