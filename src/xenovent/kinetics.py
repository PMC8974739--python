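"""Enhancement, concentration normalization, and exponential kinetic fits.

The quantitative chain applied to each ROI time-density curve:

1. *Enhancement*: HU minus the -1000 HU of room air.
2. *Reference* E100: the maximum enhancement within the input-nostril curve
   defines 100% xenon (the nasal cavity fills with essentially pure supply
   gas, -750 HU, i.e. 250 HU of enhancement on the mixed image).
3. *Concentration*: the ratio enhancement / E100, a fraction of full xenon.
4. *Kinetics*: first-order exponential fits of the wash-in
   (``c(t) = c0 + (c_ss - c0) * (1 - exp(-(t - t0)/tau))``) and wash-out
   (``c(t) = c_peak * exp(-(t - t0)/tau)``) segments, yielding the
   characteristic time constant tau per sinus and direction.

``t0`` is pinned to the protocol event that starts the transient (xenon
onset or pulsation onset), and the starting level (``c0`` / ``c_peak``) is
anchored to the observed frame nearest ``t0``: with as few as 4 washout
frames, freeing these parameters is ill-conditioned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitWindowError, InvalidReferenceError
from .roi import TimeDensityCurve

__all__ = [
    "ConcentrationCurve",
    "KineticFit",
    "enhancement",
    "reference_enhancement",
    "to_concentration",
    "fit_washin",
    "fit_washout",
    "summarize",
]

logger = logging.getLogger(__name__)

ROOM_AIR_HU = -1000.0
#: Noise can push normalized concentrations slightly past 1; values are
#: capped here before fitting.
C_CAP = 1.1
TAU_BOUNDS = (0.1, 1000.0)


@dataclass
class ConcentrationCurve:
    """Fractional xenon concentration of one ROI over time."""

    roi_name: str
    times: np.ndarray
    c: np.ndarray
    e100_hu: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        if self.times.shape != self.c.shape:
            raise ValueError("times and c must have equal length")
        if not np.all(np.isfinite(self.c)):
            raise ValueError("concentrations must be finite")
        if self.e100_hu <= 0:
            raise InvalidReferenceError(f"e100_hu must be > 0, got {self.e100_hu}")

    @property
    def peak(self) -> float:
        return float(self.c.max()) if self.c.size else float("nan")


@dataclass
class KineticFit:
    """Result of one exponential fit (one ROI, one direction)."""

    roi_name: str
    direction: str            # "wash_in" | "wash_out"
    window: tuple[float, float]
    t0: float
    tau_s: float              # nan when not converged
    level: float              # c_ss for wash-in, c_peak for wash-out
    rmse: float
    n_points: int
    converged: bool


def enhancement(hu):
    """Xenon enhancement in HU: difference to the -1000 HU of room air."""
    return np.asarray(hu, dtype=float) - ROOM_AIR_HU


def reference_enhancement(nostril_curve: TimeDensityCurve) -> float:
    """E100: maximum enhancement within the input-nostril curve.

    A non-positive result (e.g. a curve stuck at -1000 HU, meaning xenon
    never arrived) is returned as-is but logged as an invalid reference;
    :func:`to_concentration` will reject it.
    """
    if nostril_curve.hu.size == 0 or not np.any(np.isfinite(nostril_curve.hu)):
        raise InvalidReferenceError(
            f"nostril curve {nostril_curve.roi_name!r} holds no finite samples"
        )
    e100 = float(np.nanmax(enhancement(nostril_curve.hu)))
    if e100 <= 0:
        logger.warning(
            "reference enhancement from %r is %.3g HU (<= 0): invalid as E100",
            nostril_curve.roi_name, e100,
        )
    return e100


def to_concentration(curve: TimeDensityCurve, e100: float) -> ConcentrationCurve:
    """Normalize a TDC to fractional xenon concentration.

    Raises
    ------
    InvalidReferenceError
        If ``e100 <= 0``.
    """
    if e100 <= 0:
        raise InvalidReferenceError(
            f"cannot normalize by non-positive E100 = {e100} HU"
        )
    c = enhancement(curve.hu) / float(e100)
    return ConcentrationCurve(curve.roi_name, curve.times, c, float(e100))


def _select_window(curve: ConcentrationCurve, window, min_points=3):
    t0_w, t1_w = window
    times = curve.times
    if times.size == 0 or t0_w < times[0] - 1e-9 or t1_w > times[-1] + curve_dt(curve) + 1e-9:
        raise FitWindowError(
            f"window [{t0_w}, {t1_w}] s outside curve support "
            f"[{times[0] if times.size else 'nan'}, {times[-1] if times.size else 'nan'}] s"
        )
    sel = (times >= t0_w - 1e-9) & (times <= t1_w + 1e-9)
    if sel.sum() < min_points:
        raise FitWindowError(
            f"window [{t0_w}, {t1_w}] s holds {int(sel.sum())} frames; need >= {min_points}"
        )
    return times[sel], np.minimum(curve.c[sel], C_CAP)


def curve_dt(curve: ConcentrationCurve) -> float:
    return float(np.median(np.diff(curve.times))) if curve.times.size > 1 else 0.0


def _anchor_value(curve: ConcentrationCurve, t0: float) -> float:
    i = int(np.argmin(np.abs(curve.times - t0)))
    return float(min(curve.c[i], C_CAP))


def _log_linear_tau(t, y, level, floor=1e-9):
    """Initial tau from a log-linear regression of (level - y) vs t."""
    resid = level - y
    ok = resid > max(floor, 1e-3 * max(abs(level), 1.0))
    if ok.sum() >= 2:
        slope = np.polyfit(t[ok], np.log(resid[ok]), 1)[0]
        if slope < 0:
            return float(np.clip(-1.0 / slope, *TAU_BOUNDS))
    return 10.0


def fit_washin(
    curve: ConcentrationCurve,
    window: tuple[float, float],
    t0: float,
) -> KineticFit:
    """Fit ``c(t) = c0 + (c_ss - c0)(1 - exp(-(t - t0)/tau))`` on ``window``.

    ``c0`` is fixed to the observed value at the frame nearest ``t0``; free
    parameters are ``tau`` (bounded to [0.1, 1000] s) and ``c_ss``.  A flat
    curve or optimizer failure yields ``converged=False`` rather than an
    exception.

    Raises
    ------
    FitWindowError
        Window outside the curve, or fewer than 3 frames inside it.
    """
    t, y = _select_window(curve, window)
    c0 = _anchor_value(curve, t0)
    n = t.size

    if np.ptp(y) < 1e-10:
        return KineticFit(curve.roi_name, "wash_in", tuple(window), t0,
                          float("nan"), float(np.mean(y)), 0.0, n, False)

    c_ss0 = float(np.clip(y.max(), c0 + 1e-3, 1.5))
    tau0 = _log_linear_tau(t, y, c_ss0)

    def resid(p):
        tau, c_ss = p
        return c0 + (c_ss - c0) * (1.0 - np.exp(-(t - t0) / tau)) - y

    try:
        res = least_squares(
            resid, x0=[tau0, c_ss0],
            bounds=([TAU_BOUNDS[0], -0.5], [TAU_BOUNDS[1], 1.5]),
            method="trf",
        )
        ok = bool(res.success)
        tau_hat, c_ss_hat = (float(res.x[0]), float(res.x[1]))
        rmse = float(np.sqrt(np.mean(res.fun ** 2)))
    except Exception:  # optimizer failure -> unconverged fit, not an error
        ok, tau_hat, c_ss_hat, rmse = False, float("nan"), float("nan"), float("nan")
    return KineticFit(curve.roi_name, "wash_in", tuple(window), t0,
                      tau_hat if ok else float("nan"), c_ss_hat, rmse, n, ok)


def fit_washout(
    curve: ConcentrationCurve,
    window: tuple[float, float],
    t0: float,
) -> KineticFit:
    """Fit ``c(t) = c_peak * exp(-(t - t0)/tau)`` on ``window``.

    ``c_peak`` is fixed to the observed value at the frame nearest ``t0``;
    the single free parameter is ``tau``.  Same window/convergence contract
    as :func:`fit_washin`.
    """
    t, y = _select_window(curve, window)
    c_peak = _anchor_value(curve, t0)
    n = t.size

    if np.ptp(y) < 1e-10 or abs(c_peak) < 1e-9:
        return KineticFit(curve.roi_name, "wash_out", tuple(window), t0,
                          float("nan"), c_peak, 0.0, n, False)

    # log-linear init on y/c_peak where positive
    ratio = y / c_peak
    ok_r = ratio > 1e-6
    if ok_r.sum() >= 2:
        slope = np.polyfit(t[ok_r], np.log(ratio[ok_r]), 1)[0]
        tau0 = float(np.clip(-1.0 / slope, *TAU_BOUNDS)) if slope < 0 else 10.0
    else:
        tau0 = 10.0

    def resid(p):
        (tau,) = p
        return c_peak * np.exp(-(t - t0) / tau) - y

    try:
        res = least_squares(resid, x0=[tau0], bounds=([TAU_BOUNDS[0]], [TAU_BOUNDS[1]]),
                            method="trf")
        ok = bool(res.success)
        tau_hat = float(res.x[0])
        rmse = float(np.sqrt(np.mean(res.fun ** 2)))
    except Exception:
        ok, tau_hat, rmse = False, float("nan"), float("nan")
    return KineticFit(curve.roi_name, "wash_out", tuple(window), t0,
                      tau_hat if ok else float("nan"), c_peak, rmse, n, ok)


def summarize(
    fits: Iterable[KineticFit],
    curves: Mapping[str, ConcentrationCurve] | Sequence[ConcentrationCurve],
) -> pd.DataFrame:
    """One row per (ROI, direction): tau, level, whole-series peak, rmse.

    Levels, peaks and rmse are reported in percent (concentrations are
    fractions internally).  Duplicate (ROI, direction) entries keep the last
    fit and log a warning.
    """
    if not isinstance(curves, Mapping):
        curves = {c.roi_name: c for c in curves}
    rows: dict[tuple[str, str], dict] = {}
    for f in fits:
        key = (f.roi_name, f.direction)
        if key in rows:
            logger.warning("duplicate fit for %s/%s: keeping the last one", *key)
        peak = curves[f.roi_name].peak if f.roi_name in curves else float("nan")
        rows[key] = {
            "roi": f.roi_name,
            "direction": f.direction,
            "tau_s": f.tau_s,
            "level_pct": 100.0 * f.level,
            "peak_pct": 100.0 * peak,
            "rmse_pct": 100.0 * f.rmse,
            "n_points": f.n_points,
            "converged": f.converged,
        }
    cols = ["roi", "direction", "tau_s", "level_pct", "peak_pct",
            "rmse_pct", "n_points", "converged"]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(list(rows.values()), columns=cols)
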