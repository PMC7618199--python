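"""Time-optimal gradient waveform synthesis under amplitude and slew limits.

Given a geometric k-space curve, find the minimum-duration traversal whose
gradient vector magnitude stays below ``g_max`` and whose vector slew rate
stays below ``s_max`` (time-optimal path-following design).

Units used throughout: k in 1/mm, gradients in mT/m, slew in T/m/s
(numerically equal to mT/m/ms), time in ms.  The gyromagnetic ratio gamma is
given in kHz/mT; internally the conversion ``k' = gamma_eff * g`` uses
``gamma_eff = gamma / 1000`` in (1/mm) per (mT/m * ms).

Algorithm: the curve is re-parameterized by arc length s; the speed
``v(s) = |dk/dt|`` is bounded pointwise by the amplitude limit
``gamma_eff*g_max`` and the centripetal constraint ``v^2 <= a_max * R`` (R =
curvature radius, a_max = gamma_eff*s_max); a forward and a backward pass
integrate ``v dv/ds = a_tan`` with the tangential acceleration bounded by
``sqrt(a_max^2 - kappa^2 v^4)``, starting from v=0 at the k-space origin and
(by default) ending at v=0.  Time follows from t(s) = integral ds/v.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cones import BaseConeCurve

GAMMA_PROTON_KHZ_PER_MT = 42.5764  # not stated by the protocol; proton default


class GeometryError(ValueError):
    """Degenerate input curve (zero length or too few points)."""


@dataclass(frozen=True)
class HardwareLimits:
    """Gradient system limits and raster timing.

    Defaults follow a deliberately conservative protocol (peripheral-nerve
    stimulation and gradient-imperfection headroom): g_max = 11.64 mT/m,
    s_max = 61.54 T/m/s.
    """

    g_max: float = 11.64       # mT/m
    s_max: float = 61.54       # T/m/s == mT/m/ms
    raster_time: float = 10.0  # us
    gamma: float = GAMMA_PROTON_KHZ_PER_MT  # kHz/mT

    def __post_init__(self) -> None:
        for name in ("g_max", "s_max", "raster_time", "gamma"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")

    @property
    def gamma_eff(self) -> float:
        """gamma in (1/mm) per (mT/m * ms)."""
        return self.gamma * 1e-3

    @property
    def v_max(self) -> float:
        """Maximum k-space speed, 1/mm per ms."""
        return self.gamma_eff * self.g_max

    @property
    def a_max(self) -> float:
        """Maximum k-space acceleration, 1/mm per ms^2."""
        return self.gamma_eff * self.s_max


@dataclass(frozen=True)
class GradientWaveform:
    """Realized time-sampled readout.

    Attributes
    ----------
    t : (N,) array
        Time samples in ms, uniform at the raster time, starting at 0.
    g : (N-1, 3) array
        Piecewise-constant gradient over each raster interval, mT/m; exactly
        reproduces the k samples via k[i+1] = k[i] + gamma_eff*g[i]*dt.
    k : (N, 3) array
        Cumulative k-space positions, 1/mm; k[0] = 0.
    limits : HardwareLimits
    duration_ms : float
        Total traversal duration (t[-1]).
    """

    t: np.ndarray
    g: np.ndarray
    k: np.ndarray
    limits: HardwareLimits
    duration_ms: float

    def max_gradient(self) -> float:
        """Maximum gradient vector magnitude, mT/m."""
        return float(np.max(np.linalg.norm(self.g, axis=1)))

    def max_slew(self) -> float:
        """Maximum vector slew rate between consecutive raster samples, T/m/s.

        Includes the initial ramp from zero gradient.
        """
        dt = self.limits.raster_time * 1e-3
        g_ext = np.vstack([np.zeros(3), self.g])
        return float(np.max(np.linalg.norm(np.diff(g_ext, axis=0), axis=1)) / dt)


def _fit_curve_spline(points: np.ndarray):
    """Cubic-spline representation of the curve vs chord arc length.

    Prepends the k-space origin if absent (center-out readout).  Returns
    (spline, total_arclength); chord length on a dense input approximates
    true arc length well, and the spline gives smooth derivatives for
    curvature estimation.
    """
    from scipy.interpolate import CubicSpline

    pts = np.vstack([np.zeros(3), points]) if np.linalg.norm(points[0]) > 0 else points
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(s[-1])
    if total <= 0:
        raise GeometryError("curve has zero arc length")
    keep = np.concatenate([[True], np.diff(s) > 0])
    spline = CubicSpline(s[keep], pts[keep], axis=0)
    return spline, total


def _curvature_from_spline(spline, s_uniform: np.ndarray) -> np.ndarray:
    """Unsigned curvature |k' x k''| / |k'|^3 from spline derivatives."""
    d1 = spline(s_uniform, 1)
    d2 = spline(s_uniform, 2)
    num = np.linalg.norm(np.cross(d1, d2), axis=1)
    den = np.maximum(np.linalg.norm(d1, axis=1) ** 3, 1e-300)
    return num / den


def time_optimal_waveform(
    curve: BaseConeCurve,
    limits: HardwareLimits,
    n_arc: int = 20000,
    end_velocity: str = "zero",
    safety: float = 0.998,
) -> GradientWaveform:
    """Minimum-duration traversal of ``curve`` under the hardware limits.

    Parameters
    ----------
    curve : BaseConeCurve
        Geometry to traverse, center-out (origin prepended if absent).
    limits : HardwareLimits
    n_arc : int
        Arc-length grid resolution for the speed-profile integration.
    end_velocity : {"zero", "free"}
        Whether the k-space speed must return to zero at the end of the
        readout ("zero", default) or may end at the pointwise cap ("free").
    safety : float
        Design derating (< 1) applied to both limits inside the solver so
        the rasterized waveform honors the full limits after discretization.

    Raises
    ------
    GeometryError
        If the curve has fewer than 2 distinct points or zero length.
    """
    pts = np.asarray(curve.points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise GeometryError("curve must have >= 2 points of dimension 3")
    if end_velocity not in ("zero", "free"):
        raise ValueError(f"end_velocity must be 'zero' or 'free', got {end_velocity!r}")

    spline, total = _fit_curve_spline(pts)
    s_uniform = np.linspace(0.0, total, n_arc)
    ds = total / (n_arc - 1)
    kappa = _curvature_from_spline(spline, s_uniform)

    v_lim = safety * limits.v_max
    a_lim = safety * limits.a_max

    # pointwise speed cap: amplitude limit and centripetal slew limit
    with np.errstate(divide="ignore"):
        v_cent = np.sqrt(np.where(kappa > 0, a_lim / np.maximum(kappa, 1e-300), np.inf))
    v_cap = np.minimum(v_lim, v_cent)

    def a_tan(v: float, k: float) -> float:
        rem = a_lim * a_lim - (k * v * v) ** 2
        return float(np.sqrt(max(rem, 0.0)))

    v = np.empty(n_arc)
    v[0] = 0.0
    for i in range(n_arc - 1):
        a = a_tan(v[i], kappa[i])
        v[i + 1] = min(v_cap[i + 1], np.sqrt(v[i] ** 2 + 2.0 * a * ds))
    if end_velocity == "zero":
        v[-1] = 0.0
    else:
        v[-1] = min(v[-1], v_cap[-1])
    for i in range(n_arc - 2, -1, -1):
        a = a_tan(v[i + 1], kappa[i + 1])
        v[i] = min(v[i], np.sqrt(v[i + 1] ** 2 + 2.0 * a * ds))

    # time along the path; Delta t = 2 ds / (v_i + v_{i+1}) is exact for
    # constant tangential acceleration over the step (handles v=0 endpoints)
    vsum = v[:-1] + v[1:]
    if np.any(vsum <= 0):
        raise GeometryError("speed profile collapsed to zero inside the curve")
    t_of_s = np.concatenate([[0.0], np.cumsum(2.0 * ds / vsum)])
    duration = float(t_of_s[-1])

    # rasterize: uniform time grid, invert t(s) exactly under the piecewise
    # constant-acceleration model (s quadratic in t within each segment),
    # then evaluate the spline at the resulting arc lengths
    dt = limits.raster_time * 1e-3  # ms
    n_t = int(np.ceil(duration / dt)) + 1
    t_grid = np.minimum(np.arange(n_t) * dt, duration)
    seg = np.clip(np.searchsorted(t_of_s, t_grid, side="right") - 1, 0, n_arc - 2)
    tau = t_grid - t_of_s[seg]
    dt_seg = np.maximum(t_of_s[seg + 1] - t_of_s[seg], 1e-300)
    a_seg = (v[seg + 1] - v[seg]) / dt_seg
    s_grid = np.clip(s_uniform[seg] + v[seg] * tau + 0.5 * a_seg * tau * tau, 0.0, total)
    k_t = spline(s_grid)
    g = np.diff(k_t, axis=0) / (limits.gamma_eff * dt)

    return GradientWaveform(t=t_grid, g=g, k=k_t, limits=limits, duration_ms=duration)


def resample_adc(wave: GradientWaveform, dwell: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample k-space positions at ADC dwell times.

    Parameters
    ----------
    wave : GradientWaveform
    dwell : float
        ADC dwell time in us; may subdivide or exceed the raster time.

    Returns
    -------
    k_samples : (M, 3) array, 1/mm
    t_samples : (M,) array, ms
        M = floor(duration / dwell) + 1 samples (including t = 0, the
        k-space center of the center-out readout).
    """
    if dwell <= 0:
        raise ValueError(f"dwell must be > 0 us, got {dwell}")
    dwell_ms = dwell * 1e-3
    n = int(np.floor(wave.duration_ms / dwell_ms + 1e-9)) + 1
    t_samples = np.arange(n) * dwell_ms
    k_samples = np.column_stack([
        np.interp(t_samples, wave.t, wave.k[:, d]) for d in range(3)
    ])
    return k_samples, t_samples


def waveform_to_hdf5(wave: GradientWaveform, path, dwell_us: float | None = None) -> None:
    """Write /waveform/g and /waveform/k with raster/duration attributes."""
    import h5py

    with h5py.File(path, "a") as f:
        for name in ("waveform/g", "waveform/k"):
            if name in f:
                del f[name]
        f.create_dataset("waveform/g", data=wave.g)
        ds = f.create_dataset("waveform/k", data=wave.k)
        grp = f["waveform"]
        grp.attrs["raster_us"] = wave.limits.raster_time
        grp.attrs["duration_ms"] = wave.duration_ms
        if dwell_us is not None:
            grp.attrs["dwell_us"] = dwell_us


def waveform_to_csv(wave: GradientWaveform, path) -> None:
    """CSV mirror (t_ms, gx, gy, gz, kx, ky, kz) for small exports."""
    import pandas as pd

    g_ext = np.vstack([wave.g, wave.g[-1]])
    pd.DataFrame({
        "t_ms": wave.t,
        "gx_mT_m": g_ext[:, 0], "gy_mT_m": g_ext[:, 1], "gz_mT_m": g_ext[:, 2],
        "kx_per_mm": wave.k[:, 0], "ky_per_mm": wave.k[:, 1], "kz_per_mm": wave.k[:, 2],
    }).to_csv(path, index=False)
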