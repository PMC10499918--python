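"""Tilt averaging, TS-length regression, relative frequency response, and
between-species morphometry statistics.

Orientation is modelled as a Gaussian over incidence angle theta, truncated to
the 65-115 degree validity range of the ray model and renormalized on the
computation grid.  Backscatter is always averaged in the linear domain
(sigma_bs) and converted to TS afterwards.  TS-length relations follow the
two standard forms TS = m log10(L) + b (free slope) and
TS = 20 log10(L) + b20 (slope fixed to 20), with L the total length in cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import DomainError, InsufficientDataError
from .krm import THETA_MAX, THETA_MIN, BackscatterGrid
from .shapes import FishModel, measure_morphometrics

__all__ = [
    "TiltDistribution",
    "tilt_averaged_sigma",
    "TSLengthModel",
    "TSLengthResult",
    "fit_ts_length",
    "RFICurve",
    "relative_frequency_response",
    "AllometryResult",
    "allometry_test",
    "compare_species_morphometrics",
]


@dataclass(frozen=True)
class TiltDistribution:
    """Truncated-Gaussian orientation model on [65, 115] degrees.

    ``mean``/``sd`` are in degrees of incidence angle theta (broadside = 90);
    the equivalent fish tilt is t = 90 - theta.
    """

    mean: float
    sd: float
    support: Tuple[float, float] = (THETA_MIN, THETA_MAX)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise DomainError("tilt sd must be >= 0")
        lo, hi = self.support
        if not hi > lo:
            raise DomainError("empty tilt support")

    @property
    def label(self) -> str:
        return f"{self.mean:g}° ± {self.sd:g}°"

    def weights(self, theta_deg: np.ndarray) -> np.ndarray:
        """Non-negative weights at grid nodes, truncated and renormalized.

        Nodes outside the support get zero weight.  A vanishing sd collapses
        the distribution onto the node nearest the mean.
        """
        theta = np.asarray(theta_deg, dtype=float)
        lo, hi = self.support
        inside = (theta >= lo - 1e-12) & (theta <= hi + 1e-12)
        if not np.any(inside):
            raise DomainError(
                "tilt grid has no nodes inside the support "
                f"[{lo:g}, {hi:g}] degrees"
            )
        w = np.zeros_like(theta)
        if self.sd > 0:
            w[inside] = stats.norm.pdf(theta[inside], self.mean, self.sd)
        total = w.sum()
        if total <= 0.0:
            # delta limit (or extreme truncation): nearest in-support node
            idx = np.where(inside)[0]
            w[:] = 0.0
            w[idx[np.argmin(np.abs(theta[idx] - self.mean))]] = 1.0
            total = 1.0
        return w / total


def tilt_averaged_sigma(
    grid: BackscatterGrid, dist: TiltDistribution
) -> np.ndarray:
    """Orientation-averaged backscattering cross-section sigma_bs(f) (m^2).

    The average is taken strictly in the linear domain over the grid's tilt
    axis with the distribution's truncated, renormalized weights.
    """
    w = dist.weights(grid.theta_deg)
    return grid.sigma_bs @ w


# -- TS-length regression --------------------------------------------------


@dataclass(frozen=True)
class TSLengthResult:
    """TS-length regression coefficients (free slope and slope fixed to 20).

    All dB values are dB re 1 m^2; lengths are total length in cm.
    """

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r2: float
    b20: Optional[float]
    b20_se: Optional[float]
    r2_20: Optional[float]
    resid_se: float
    n: int
    fixed_slope: Optional[float]

    def predict(self, tl_cm) -> np.ndarray:
        """Predicted TS from the free-slope fit."""
        return self.slope * np.log10(np.asarray(tl_cm, dtype=float)) + self.intercept

    def predict_fixed(self, tl_cm) -> np.ndarray:
        if self.b20 is None:
            raise DomainError("no fixed-slope fit in this result")
        return self.fixed_slope * np.log10(
            np.asarray(tl_cm, dtype=float)
        ) + self.b20

    def summary(self) -> str:
        lines = [
            "TS-length regression (TS = m log10(L) + b)",
            f"  n          : {self.n}",
            f"  m          : {self.slope:.2f}",
            f"  b          : {self.intercept:.2f} dB re 1 m^2 "
            f"(s.e. {self.intercept_se:.2f})",
            f"  r^2        : {self.r2:.2f}",
        ]
        if self.b20 is not None:
            lines += [
                f"fixed slope {self.fixed_slope:g}:",
                f"  b{self.fixed_slope:g}        : {self.b20:.2f} dB re 1 m^2 "
                f"(s.e. {self.b20_se:.2f})",
                f"  r^2        : {self.r2_20:.2f}",
            ]
        return "\n".join(lines)


class TSLengthModel:
    """OLS of TS (dB) on log10 total length (cm), statsmodels-backed."""

    def __init__(self, tl_cm: Sequence[float], ts_db: Sequence[float]):
        tl = np.asarray(tl_cm, dtype=float)
        ts = np.asarray(ts_db, dtype=float)
        if tl.shape != ts.shape or tl.ndim != 1:
            raise DomainError("TL and TS must be 1-D arrays of equal length")
        if np.any(tl <= 0):
            raise DomainError("total lengths must be > 0")
        self.tl_cm = tl
        self.ts_db = ts

    def fit(self, fixed_slope: Optional[float] = None) -> TSLengthResult:
        n = self.tl_cm.size
        if n < 3:
            raise InsufficientDataError(
                f"need at least 3 specimens for the free-slope fit (got {n})"
            )
        x = np.log10(self.tl_cm)
        y = self.ts_db
        res = sm.OLS(y, sm.add_constant(x)).fit()
        intercept, slope = res.params
        se_b, se_m = res.bse
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = float(res.rsquared) if sst > 0 else 0.0

        b20 = b20_se = r2_20 = None
        if fixed_slope is not None:
            offsets = y - fixed_slope * x
            b20 = float(np.mean(offsets))
            b20_se = float(
                np.std(offsets, ddof=1) / math.sqrt(n) if n > 1 else 0.0
            )
            ss_res_fixed = float(np.sum((y - fixed_slope * x - b20) ** 2))
            r2_20 = 1.0 - ss_res_fixed / sst if sst > 0 else 0.0
        return TSLengthResult(
            slope=float(slope),
            intercept=float(intercept),
            slope_se=float(se_m),
            intercept_se=float(se_b),
            r2=r2,
            b20=b20,
            b20_se=b20_se,
            r2_20=r2_20,
            resid_se=float(np.sqrt(res.mse_resid)) if n > 2 else 0.0,
            n=n,
            fixed_slope=fixed_slope,
        )


def fit_ts_length(
    pairs: Iterable[Tuple[float, float]], fixed_slope: Optional[float] = 20.0
) -> TSLengthResult:
    """Fit TS = m log10(L) + b (and TS = 20 log10(L) + b20) to (TL, TS) pairs."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DomainError("pairs must be (TL_cm, TS_dB) tuples")
    return TSLengthModel(arr[:, 0], arr[:, 1]).fit(fixed_slope=fixed_slope)


# -- relative frequency response ------------------------------------------


@dataclass(frozen=True)
class RFICurve:
    """Per-fish and cohort-mean frequency ratios r(f) = sigma(f)/sigma(38 kHz)."""

    f_khz: Tuple[float, ...]
    per_fish: np.ndarray  # shape (n_fish, n_freq)
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "f_khz": self.f_khz,
                "r_mean": self.mean,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def relative_frequency_response(
    sigma_per_fish: np.ndarray,
    f_khz: Sequence[float] = (38.0, 70.0, 120.0, 200.0),
    ref_khz: float = 38.0,
) -> RFICurve:
    """Relative frequency response r_i(f) = sigma_i(f) / sigma_i(38 kHz).

    ``sigma_per_fish`` holds one row per fish of (tilt-averaged or broadside)
    sigma_bs at the discrete survey frequencies.  The cohort band is the
    parametric mean +/- 1.96 standard errors across fish.
    """
    sig = np.atleast_2d(np.asarray(sigma_per_fish, dtype=float))
    freqs = tuple(float(f) for f in f_khz)
    if sig.shape[1] != len(freqs):
        raise DomainError("sigma array width must match the frequency list")
    if ref_khz not in freqs:
        raise DomainError(f"reference frequency {ref_khz} kHz not in the list")
    j_ref = freqs.index(ref_khz)
    ref = sig[:, j_ref]
    if np.any(ref <= 0):
        raise DomainError("sigma at the reference frequency must be > 0")
    ratios = sig / ref[:, None]
    n = sig.shape[0]
    mean = ratios.mean(axis=0)
    se = ratios.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros_like(mean)
    return RFICurve(
        f_khz=freqs,
        per_fish=ratios,
        mean=mean,
        ci_low=mean - 1.96 * se,
        ci_high=mean + 1.96 * se,
        n=n,
    )


# -- allometry and species comparison -------------------------------------


@dataclass(frozen=True)
class AllometryResult:
    """Log-log growth fit of dorsal area on TL with a test against isometry."""

    slope: float
    slope_se: float
    intercept: float
    r2: float
    t_stat: float
    p_value: float
    n: int
    isometric_slope: float = 2.0


def allometry_test(
    areas_mm2: Sequence[float],
    tl_cm: Sequence[float],
    isometric_slope: float = 2.0,
) -> AllometryResult:
    """OLS of log10(area) on log10(TL), two-sided t-test of slope vs 2.

    Isometric growth of an area scales as length squared; the test reports
    whether the fitted log-log slope differs from that exponent.
    """
    area = np.asarray(areas_mm2, dtype=float)
    tl = np.asarray(tl_cm, dtype=float)
    if area.shape != tl.shape or area.ndim != 1:
        raise DomainError("areas and TLs must be 1-D arrays of equal length")
    if area.size < 3:
        raise InsufficientDataError("need at least 3 specimens")
    if np.any(area <= 0) or np.any(tl <= 0):
        raise DomainError("areas and lengths must be > 0")
    x = np.log10(tl)
    y = np.log10(area)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    se = res.bse[1]
    noiseless = se == 0.0 or res.rsquared > 1.0 - 1e-12
    if noiseless:  # exact power law: the test degenerates to slope == exponent
        exact = math.isclose(slope, isometric_slope, abs_tol=1e-9)
        t_stat = 0.0 if exact else math.inf * float(np.sign(slope - isometric_slope))
        p = 1.0 if exact else 0.0
    else:
        t_stat = (slope - isometric_slope) / se
        p = 2.0 * stats.t.sf(abs(t_stat), df=res.df_resid)
    return AllometryResult(
        slope=float(slope),
        slope_se=float(se),
        intercept=float(intercept),
        r2=float(res.rsquared),
        t_stat=float(t_stat),
        p_value=float(p),
        n=area.size,
    )


_MEASURES = ("sbl", "sbh", "sbw", "dorsal_area", "volume")


def _morphometry_frame(cohort: Sequence[FishModel]) -> pd.DataFrame:
    rows = []
    for fish in cohort:
        if fish.bladder is None:
            continue  # deflated specimens are excluded from the comparison
        m = measure_morphometrics(fish)
        rows.append(
            {
                "tl_cm": fish.total_length_cm,
                "sbl": m.sbl,
                "sbh": m.sbh,
                "sbw": m.sbw,
                "dorsal_area": m.dorsal_area,
                "volume": m.volume,
            }
        )
    return pd.DataFrame(rows)


def compare_species_morphometrics(
    cohort_a: Sequence[FishModel], cohort_b: Sequence[FishModel]
) -> pd.DataFrame:
    """Length-corrected between-species comparison of swimbladder measures.

    Each measure (sbl, sbh, sbw, dorsal area, volume) is regressed on TL over
    the pooled cohorts; the residuals — relative swimbladder sizes with the
    common length effect removed — are compared between cohorts with a Welch
    two-sample t-test.  (A common regression is essential: residuals of
    per-cohort fits are zero-mean within each cohort by construction and can
    carry no between-species signal.)  Returns one row per measure with t,
    df, p and the mean residual difference (cohort A minus cohort B).
    """
    fa = _morphometry_frame(cohort_a)
    fb = _morphometry_frame(cohort_b)
    if len(fa) < 3 or len(fb) < 3:
        raise InsufficientDataError(
            "each cohort needs >= 3 specimens with inflated swimbladders"
        )
    pooled = pd.concat([fa, fb], ignore_index=True)
    x = sm.add_constant(pooled["tl_cm"].to_numpy())
    rows = []
    for measure in _MEASURES:
        resid = np.asarray(sm.OLS(pooled[measure].to_numpy(), x).fit().resid)
        ra = resid[: len(fa)]
        rb = resid[len(fa):]
        res = stats.ttest_ind(ra, rb, equal_var=False)
        rows.append(
            {
                "measure": measure,
                "t": float(res.statistic),
                "df": float(res.df),
                "p_value": float(res.pvalue),
                "mean_resid_diff": float(ra.mean() - rb.mean()),
            }
        )
    return pd.DataFrame(rows)
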