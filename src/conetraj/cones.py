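"""Two-stage parametric cone trajectory geometry.

A single readout ("shot") traces a center-out curve on a cone in 3D k-space.
The curve is controlled by the cone half-angle ``theta``, a stage-separation
point ``m``, a curvature power ``n`` and a twist scaling ``A``:

* stage 1 (0 < alpha <= m): a conventional fixed-angle cone — the transverse
  radius grows linearly with alpha, scaled by ``m**(n-1)`` so that the two
  stages join continuously;
* stage 2 (m < alpha <= 1): the cone angle opens with radial distance — the
  transverse radius grows as ``alpha**n``.

Both stages share the axial law ``k_max*cos(theta)*alpha`` and the azimuthal
sweep ``A*alpha``, so the endpoint always sits at radius ``k_max`` at angle
``theta`` from the cone axis.  Angles are accepted in degrees at every public
interface and converted to radians internally.

The geometry is purely parametric in alpha; the physical time
parameterization under gradient amplitude/slew limits is handled by
:mod:`conetraj.gradients`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .gradients import HardwareLimits


class ConeParameterError(ValueError):
    """A cone parameter is outside its valid range (names the field)."""


class InfeasibleDurationError(ValueError):
    """Requested readout duration is shorter than the zero-twist minimum."""

    def __init__(self, target_ms: float, minimum_ms: float):
        self.target_ms = target_ms
        self.minimum_ms = minimum_ms
        super().__init__(
            f"target readout duration {target_ms:.4f} ms is shorter than the "
            f"A=0 minimum of {minimum_ms:.4f} ms for this geometry"
        )


@dataclass(frozen=True)
class ConeParams:
    """Free parameters of the two-stage cone design.

    Parameters
    ----------
    theta : float
        Cone half-angle between the trajectory endpoint and the central
        axis, in degrees.  ``theta = 0`` degenerates to a radial spoke.
    m : float
        Stage-separation point in [0, 1].  ``m = 0`` is the single-stage
        design (pure ``alpha**n`` law); ``m = 1`` is a pure fixed-angle cone.
    n : float
        Curvature power (>= 1) of the stage-2 radial law.
    A : float
        Twist scaling — total azimuthal sweep in radians over alpha in [0,1].
        Larger A lengthens the curve, accommodating longer readouts.
    k_max : float
        Maximum spatial frequency in 1/mm.  Nominal isotropic resolution is
        ``1 / (2 * k_max)`` mm.
    readout_duration : float
        Target readout time in ms (used by :func:`solve_twist_scaling`).
    """

    theta: float
    m: float
    n: float
    A: float
    k_max: float
    readout_duration: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta < 90.0):
            raise ConeParameterError(f"theta must be in [0, 90) degrees, got {self.theta}")
        if not (0.0 <= self.m <= 1.0):
            raise ConeParameterError(f"m must be in [0, 1], got {self.m}")
        if not self.n >= 1.0:
            raise ConeParameterError(f"n must be >= 1, got {self.n}")
        if not self.A >= 0.0:
            raise ConeParameterError(f"A must be >= 0, got {self.A}")
        if not (np.isfinite(self.k_max) and self.k_max > 0.0):
            raise ConeParameterError(f"k_max must be finite and > 0, got {self.k_max}")
        if not (np.isfinite(self.readout_duration) and self.readout_duration > 0.0):
            raise ConeParameterError(
                f"readout_duration must be finite and > 0, got {self.readout_duration}"
            )

    @property
    def theta_rad(self) -> float:
        return float(np.deg2rad(self.theta))

    @property
    def nominal_resolution_mm(self) -> float:
        """Nominal isotropic resolution 1/(2*k_max) in mm."""
        return 1.0 / (2.0 * self.k_max)

    @staticmethod
    def for_resolution(theta: float, m: float, n: float, A: float,
                       resolution_mm: float, readout_duration: float) -> "ConeParams":
        """Build parameters with k_max set for a nominal isotropic resolution."""
        if resolution_mm <= 0:
            raise ConeParameterError(f"resolution_mm must be > 0, got {resolution_mm}")
        return ConeParams(theta=theta, m=m, n=n, A=A,
                          k_max=1.0 / (2.0 * resolution_mm),
                          readout_duration=readout_duration)


@dataclass(frozen=True)
class BaseConeCurve:
    """Geometric curve k(alpha) of one shot, before any rotation.

    Attributes
    ----------
    alpha : (N,) array
        Monotonically increasing curve parameter in (0, 1].
    points : (N, 3) array
        k-space coordinates in 1/mm, in a frame whose third basis vector is
        the cone axis (columns of ``basis`` are (k_x_hat, k_y_hat, k_z_hat)).
    basis : (3, 3) array
        Orthonormal axis vectors; identity for the canonical z-axis cone.
    params : ConeParams
        The generating parameters.
    """

    alpha: np.ndarray
    points: np.ndarray
    basis: np.ndarray
    params: ConeParams

    def endpoint_radius(self) -> float:
        return float(np.linalg.norm(self.points[-1]))


def transverse_radius(params: ConeParams, alpha: np.ndarray) -> np.ndarray:
    """Transverse (off-axis) k radius at each alpha, both branches."""
    a = np.asarray(alpha, dtype=float)
    sin_t = np.sin(params.theta_rad)
    r1 = params.m ** (params.n - 1.0) * params.k_max * sin_t * a
    r2 = params.k_max * sin_t * a ** params.n
    return np.where(a <= params.m, r1, r2)


def base_cone(params: ConeParams, num_samples: int) -> BaseConeCurve:
    """Evaluate the two-stage cone curve on a uniform alpha grid.

    alpha is sampled uniformly on (0, 1] (``num_samples`` points); the
    center-out limit alpha -> 0+ maps to the k-space origin, which is
    included implicitly because the first alpha sample is 1/num_samples.

    Raises
    ------
    ConeParameterError
        If ``num_samples < 2`` or parameters are invalid.
    """
    if num_samples < 2:
        raise ConeParameterError(f"num_samples must be >= 2, got {num_samples}")
    alpha = np.linspace(0.0, 1.0, num_samples + 1)[1:]
    points = _evaluate(params, alpha)
    return BaseConeCurve(alpha=alpha, points=points, basis=np.eye(3), params=params)


def _evaluate(params: ConeParams, alpha: np.ndarray) -> np.ndarray:
    a = np.asarray(alpha, dtype=float)
    cos_t = np.cos(params.theta_rad)
    kz = params.k_max * cos_t * a
    r = transverse_radius(params, a)
    phi = params.A * a
    return np.stack([r * np.cos(phi), r * np.sin(phi), kz], axis=-1)


def stage1_cone_angle(params: ConeParams) -> float:
    """Constant half-angle (degrees) of the stage-1 fixed-angle cone.

    Equals ``arctan(m**(n-1) * tan(theta))``.  Undefined for ``m = 0``
    (single-stage design has no stage 1).
    """
    if params.m <= 0.0:
        raise ConeParameterError("stage-1 cone angle is undefined for m = 0 (single-stage design)")
    tan_stage1 = params.m ** (params.n - 1.0) * np.tan(params.theta_rad)
    return float(np.rad2deg(np.arctan(tan_stage1)))


def solve_twist_scaling(
    params: ConeParams,
    limits: "HardwareLimits",
    num_samples: int = 4000,
    rel_tol: float = 0.005,
    max_iter: int = 80,
) -> float:
    """Solve for the twist scaling A that hits the target readout duration.

    The time-optimal traversal duration of the cone (via
    :func:`conetraj.gradients.time_optimal_waveform`) is non-decreasing in A:
    more twist means a longer curve.  A bracketing + bisection search finds A
    such that the duration matches ``params.readout_duration`` within
    ``rel_tol`` (default 0.5%, inside the 1% contract).

    Raises
    ------
    InfeasibleDurationError
        If the target is shorter than the A=0 minimum duration.
    """
    from .gradients import time_optimal_waveform  # deferred: avoids import cycle

    target = params.readout_duration

    def duration_at(A: float) -> float:
        curve = base_cone(replace(params, A=A), num_samples)
        return time_optimal_waveform(curve, limits).duration_ms

    d0 = duration_at(0.0)
    if target < d0 * (1.0 - 1e-9):
        raise InfeasibleDurationError(target, d0)
    if abs(d0 - target) <= rel_tol * target:
        return 0.0

    # geometric bracket expansion, then bisection
    lo, hi = 0.0, max(2.0 * np.pi, 1.0)
    d_hi = duration_at(hi)
    n_expand = 0
    while d_hi < target and n_expand < 60:
        lo = hi
        hi *= 2.0
        d_hi = duration_at(hi)
        n_expand += 1
    if d_hi < target:
        raise RuntimeError(f"could not bracket target duration {target} ms (A up to {hi})")

    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        d_mid = duration_at(mid)
        if abs(d_mid - target) <= rel_tol * target:
            return mid
        if d_mid < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def curve_to_csv(curve: BaseConeCurve, path) -> None:
    """Write the curve as CSV with columns alpha, kx, ky, kz (1/mm)."""
    import pandas as pd

    df = pd.DataFrame({
        "alpha": curve.alpha,
        "kx": curve.points[:, 0],
        "ky": curve.points[:, 1],
        "kz": curve.points[:, 2],
    })
    df.to_csv(path, index=False)


def curve_to_hdf5(curve: BaseConeCurve, path) -> None:
    """Write the curve to HDF5 dataset /trajectory/base_curve with attributes."""
    import h5py

    with h5py.File(path, "a") as f:
        if "trajectory/base_curve" in f:
            del f["trajectory/base_curve"]
        ds = f.create_dataset("trajectory/base_curve", data=curve.points)
        ds.attrs["theta_deg"] = curve.params.theta
        ds.attrs["m"] = curve.params.m
        ds.attrs["n"] = curve.params.n
        ds.attrs["A"] = curve.params.A
        ds.attrs["kmax_per_mm"] = curve.params.k_max
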