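"""Digitized fish geometry and swimbladder morphometry.

A fish is represented by station tables traced from dorsal and lateral
radiograph projections: at each axial position ``u`` (mm, snout -> tail) the
sagittal upper and lower boundaries ``z_upper``/``z_lower`` (mm, ventral ->
dorsal) and the dorsal-view width ``w`` (mm) are recorded.  One
:class:`ShapeProfile` describes one structure (fish body or swimbladder); a
:class:`FishModel` bundles the two together with specimen metadata.

All geometry is kept in millimetres; conversion to metres happens only inside
the scattering engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .exceptions import DeflatedSpecimenError, DomainError, InvalidShapeError

__all__ = [
    "ShapeProfile",
    "MaterialSet",
    "FishModel",
    "Morphometrics",
    "resample_profile",
    "measure_morphometrics",
    "ellipsoid_volume",
]


@dataclass(frozen=True)
class MaterialSet:
    """Sound speeds (m/s) and densities (kg/m^3) of water, fish body, swimbladder.

    Defaults are the survey parameters used throughout: CTD-derived water sound
    speed and literature fish-body / swimbladder-gas properties.
    """

    c_w: float = 1509.0
    c_fb: float = 1570.0
    c_sb: float = 345.0
    rho_w: float = 1026.0
    rho_fb: float = 1070.0
    rho_sb: float = 1.24

    def __post_init__(self) -> None:
        for name in ("c_w", "c_fb", "c_sb", "rho_w", "rho_fb", "rho_sb"):
            if not getattr(self, name) > 0:
                raise DomainError(f"material parameter {name} must be > 0")


@dataclass(frozen=True)
class ShapeProfile:
    """Station-wise digitized outline of one structure (body or bladder).

    Attributes
    ----------
    u : ndarray
        Axial positions (mm), strictly increasing.
    z_upper, z_lower : ndarray
        Upper / lower sagittal boundaries (mm, ventral -> dorsal).
    w : ndarray
        Dorsal-view width (mm), >= 0.
    """

    u: np.ndarray
    z_upper: np.ndarray
    z_lower: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        zu = np.asarray(self.z_upper, dtype=float)
        zl = np.asarray(self.z_lower, dtype=float)
        w = np.asarray(self.w, dtype=float)
        if not (u.ndim == 1 and u.shape == zu.shape == zl.shape == w.shape):
            raise InvalidShapeError("station arrays must be 1-D and equal length")
        if u.size < 2:
            raise InvalidShapeError("a profile needs at least 2 stations")
        if not np.all(np.diff(u) > 0):
            raise InvalidShapeError("axial positions must be strictly increasing")
        if np.any(zu < zl - 1e-12):
            raise InvalidShapeError("z_upper must be >= z_lower at every station")
        if np.any(w < -1e-12):
            raise InvalidShapeError("widths must be non-negative")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "z_upper", zu)
        object.__setattr__(self, "z_lower", zl)
        object.__setattr__(self, "w", np.maximum(w, 0.0))

    @property
    def n_stations(self) -> int:
        return self.u.size

    @property
    def extent(self) -> float:
        """Axial extent (mm)."""
        return float(self.u[-1] - self.u[0])

    @property
    def station_spacing(self) -> Optional[float]:
        """Uniform station spacing (mm), or None when stations are non-uniform."""
        gaps = np.diff(self.u)
        if np.all(np.abs(gaps - gaps[0]) <= 1e-9):
            return float(gaps[0])
        return None

    def midline(self) -> np.ndarray:
        """Sagittal midline (z_upper + z_lower)/2 at each station."""
        return 0.5 * (self.z_upper + self.z_lower)

    def translated(self, du: float = 0.0, dz: float = 0.0) -> "ShapeProfile":
        return ShapeProfile(
            self.u + du, self.z_upper + dz, self.z_lower + dz, self.w
        )


def resample_profile(profile: ShapeProfile, du: float) -> ShapeProfile:
    """Resample a profile to uniform station spacing ``du`` (mm).

    Boundaries are linearly interpolated; both endpoints of the original axial
    extent are preserved, so the realized spacing is ``extent/(n-1)`` with
    ``n`` chosen to put the spacing as close to ``du`` as possible.
    """
    if not du > 0:
        raise DomainError("station spacing must be > 0")
    extent = profile.extent
    n = max(2, int(round(extent / du)) + 1)
    u_new = np.linspace(profile.u[0], profile.u[-1], n)
    return ShapeProfile(
        u_new,
        np.interp(u_new, profile.u, profile.z_upper),
        np.interp(u_new, profile.u, profile.z_lower),
        np.interp(u_new, profile.u, profile.w),
    )


@dataclass(frozen=True)
class FishModel:
    """A digitized specimen: body and (optionally) swimbladder profiles.

    A missing ``bladder`` marks a deflated specimen: it is representable and
    measurable for bookkeeping but excluded from acoustic computation, and
    ``body`` may be omitted for bladder-only benchmark geometries.
    """

    species: str
    total_length_cm: float
    body: Optional[ShapeProfile] = None
    bladder: Optional[ShapeProfile] = None
    note: str = ""

    def __post_init__(self) -> None:
        if not self.total_length_cm > 0:
            raise DomainError("total length must be > 0")
        if self.body is not None and self.bladder is not None:
            tol = 1e-9
            if (
                self.bladder.u[0] < self.body.u[0] - tol
                or self.bladder.u[-1] > self.body.u[-1] + tol
            ):
                raise InvalidShapeError(
                    "swimbladder must lie within the body's axial extent"
                )

    @property
    def has_bladder(self) -> bool:
        return self.bladder is not None

    def resampled(self, du: float) -> "FishModel":
        return replace(
            self,
            body=None if self.body is None else resample_profile(self.body, du),
            bladder=None
            if self.bladder is None
            else resample_profile(self.bladder, du),
        )


@dataclass(frozen=True)
class Morphometrics:
    """Swimbladder measurements of one specimen (mm / mm^2 / mm^3 / degrees)."""

    sbl: float
    sbh: float
    sbw: float
    sb_theta: float
    dorsal_area: float
    volume: float

    def as_dict(self) -> dict:
        return {
            "sbl_mm": self.sbl,
            "sbh_mm": self.sbh,
            "sbw_mm": self.sbw,
            "sb_theta_deg": self.sb_theta,
            "dorsal_area_mm2": self.dorsal_area,
            "volume_mm3": self.volume,
        }


def ellipsoid_volume(sbl: float, sbh: float, sbw: float) -> float:
    """Ellipsoid volume V = 4pi/3 (sbl/2)(sbh/2)(sbw/2), mm^3."""
    if sbl < 0 or sbh < 0 or sbw < 0:
        raise DomainError("ellipsoid axes must be non-negative")
    return 4.0 * math.pi / 3.0 * (sbl / 2.0) * (sbh / 2.0) * (sbw / 2.0)


def _line_slope(u0: float, z0: float, u1: float, z1: float) -> float:
    if u1 == u0:
        raise InvalidShapeError("degenerate axis: coincident end stations")
    return (z1 - z0) / (u1 - u0)


def measure_morphometrics(fish: FishModel) -> Morphometrics:
    """Measure the swimbladder of a specimen.

    sbl is the axial extent, sbh the maximum sagittal thickness, sbw the
    maximum dorsal width, the dorsal area the trapezoid integral of width
    over axial position, and the volume the ellipsoid formula applied to
    (sbl, sbh, sbw).  The bladder inclination sb_theta is the angle between
    the body centreline (line through the body's anterior and posterior
    mid-height points) and the line through the bladder's anterior and
    posterior midline points, positive when the bladder's anterior end sits
    higher; without a body profile the horizontal axis is the reference.
    """
    if fish.bladder is None:
        raise DeflatedSpecimenError(
            f"specimen {fish.species!r} has no inflated swimbladder"
        )
    b = fish.bladder
    sbl = b.extent
    sbh = float(np.max(b.z_upper - b.z_lower))
    sbw = float(np.max(b.w))
    area = float(np.trapezoid(b.w, b.u))

    mid = b.midline()
    slope_bl = _line_slope(b.u[0], mid[0], b.u[-1], mid[-1])
    if fish.body is not None:
        bm = fish.body.midline()
        slope_body = _line_slope(fish.body.u[0], bm[0], fish.body.u[-1], bm[-1])
    else:
        slope_body = 0.0
    # anterior end higher => bladder midline falls with u => positive angle
    theta = math.degrees(math.atan(slope_body) - math.atan(slope_bl))

    return Morphometrics(
        sbl=sbl,
        sbh=sbh,
        sbw=sbw,
        sb_theta=theta,
        dorsal_area=area,
        volume=ellipsoid_volume(sbl, sbh, sbw),
    )
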