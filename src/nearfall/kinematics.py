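"""Trunk angular kinematics from a four-package inertial measurement cluster.

An inertial measurement cluster (IMC) is a rigid assembly of four
accelerometer+gyroscope packages.  Because the packages are rigidly
connected, the spatial differences of their linear-acceleration readings
encode the angular acceleration vector of the assembly algebraically, so
no noise-amplifying numerical differentiation of the gyroscope signal is
needed.  This module provides

* the cluster solver :func:`cluster_angular_acceleration`, which inverts
  the rigid-body relation between package accelerations and the angular
  acceleration vector,
* the rigid-body forward model used as its independent oracle,
* single-sensor baselines (:func:`central_difference`,
  :func:`backward_difference`) that obtain angular acceleration by
  differencing a gyroscope channel, for IMC-vs-IMU comparisons.

Sign convention
---------------
For a rigid body rotating with angular velocity ``w`` and angular
acceleration ``alpha``, the acceleration of package *i* located at
``r_i`` relative to package 0 is::

    a_i = a_0 + alpha x r_i + w x (w x r_i)

The cluster solver closes exactly under the convention that the
geometry vectors point *from package 0 to package i*.  The convention is
pinned down by the requirement that solving the forward-modelled sample
recovers ``alpha`` exactly in the noise-free case (verified to 1e-9 by
the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

from .errors import ConditioningError, InsufficientDataError, InvalidInputError

Vec3 = np.ndarray  # shape (3,), finite components

_DT_RTOL = 1e-9


def _vec3(v: Sequence[float], name: str = "vector") -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.shape != (3,):
        raise InvalidInputError(f"{name} must have shape (3,), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} has non-finite components")
    return arr


@dataclass(frozen=True)
class ClusterGeometry:
    """Relative positions of sensor packages 1-3 with respect to package 0.

    Vectors are expressed in the cluster's orthogonal measurement frame,
    in metres.  The default geometry uses the miniaturised-cluster norms
    |r10| = 0.08 m, |r20| = 0.08 m, |r30| = 0.05 m along pairwise
    orthogonal axes.
    """

    r10: np.ndarray
    r20: np.ndarray
    r30: np.ndarray
    condition_cap: float = 1e8
    _matrix: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        r10 = _vec3(self.r10, "r10")
        r20 = _vec3(self.r20, "r20")
        r30 = _vec3(self.r30, "r30")
        object.__setattr__(self, "r10", r10)
        object.__setattr__(self, "r20", r20)
        object.__setattr__(self, "r30", r30)
        m = np.vstack(
            [np.cross(r10, r20), np.cross(r20, r30), np.cross(r30, r10)]
        )
        cond = np.linalg.cond(m)
        if not np.isfinite(cond) or cond > self.condition_cap:
            raise ConditioningError(
                f"geometry matrix condition number {cond:.3g} exceeds cap "
                f"{self.condition_cap:.3g}; relative vectors are too close "
                "to linear dependence"
            )
        object.__setattr__(self, "_matrix", m)

    @property
    def matrix(self) -> np.ndarray:
        """3x3 system matrix with rows (r10xr20)^T, (r20xr30)^T, (r30xr10)^T."""
        return self._matrix


def default_geometry() -> ClusterGeometry:
    """Miniaturised-cluster geometry: orthogonal arms of 8, 8 and 5 cm."""
    return ClusterGeometry(
        r10=np.array([0.08, 0.0, 0.0]),
        r20=np.array([0.0, 0.08, 0.0]),
        r30=np.array([0.0, 0.0, 0.05]),
    )


@dataclass
class ClusterSample:
    """One timestamped reading of the four sensor packages.

    ``a`` and ``w`` are (4, 3) arrays: linear acceleration (m/s^2) and
    angular velocity (rad/s) for packages 0..3.
    """

    t: float
    a: np.ndarray
    w: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        for name, arr in (("a", self.a), ("w", self.w)):
            if arr.shape != (4, 3):
                raise InvalidInputError(
                    f"ClusterSample.{name} must have shape (4, 3) "
                    f"(four packages), got {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise InvalidInputError(f"ClusterSample.{name} has non-finite entries")


@dataclass
class ClusterSeries:
    """Uniformly sampled sequence of cluster readings."""

    t: np.ndarray          # (N,)
    a: np.ndarray          # (N, 4, 3)
    w: np.ndarray          # (N, 4, 3)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        n = self.t.shape[0]
        if self.a.shape != (n, 4, 3) or self.w.shape != (n, 4, 3):
            raise InvalidInputError("ClusterSeries arrays have inconsistent shapes")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise InvalidInputError("ClusterSeries timestamps must strictly increase")

    def __len__(self) -> int:
        return len(self.t)

    def sample(self, i: int) -> ClusterSample:
        return ClusterSample(t=float(self.t[i]), a=self.a[i], w=self.w[i])


@dataclass
class KinematicsSeries:
    """Trunk angular kinematics on a uniform time grid.

    ``omega_y`` (rad/s) and ``alpha_y`` (rad/s^2) are the angular velocity
    and acceleration coordinates about the trunk's transverse (pitch)
    axis; full 3-vector sequences are optional.
    """

    t: np.ndarray
    omega_y: np.ndarray
    alpha_y: np.ndarray
    omega: Optional[np.ndarray] = None   # (N, 3)
    alpha: Optional[np.ndarray] = None   # (N, 3)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.omega_y = np.asarray(self.omega_y, dtype=float)
        self.alpha_y = np.asarray(self.alpha_y, dtype=float)
        n = len(self.t)
        if len(self.omega_y) != n or len(self.alpha_y) != n:
            raise InvalidInputError("KinematicsSeries arrays must have equal length")
        if n < 2:
            raise InvalidInputError("KinematicsSeries needs at least two samples")
        steps = np.diff(self.t)
        dt = steps[0]
        if dt <= 0 or not np.allclose(steps, dt, rtol=_DT_RTOL, atol=1e-12):
            bad = int(np.argmax(np.abs(steps - dt))) + 1
            raise InvalidInputError(
                f"non-uniform time grid: spacing at sample {bad} is "
                f"{steps[bad - 1]:.9g} s, expected {dt:.9g} s"
            )

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def segment(self, t0: float, t1: float) -> "KinematicsSeries":
        """Sub-series with t0 <= t <= t1 (clamped to the record)."""
        mask = (self.t >= t0 - 1e-12) & (self.t <= t1 + 1e-12)
        if mask.sum() < 2:
            raise InvalidInputError(f"segment [{t0}, {t1}] contains <2 samples")
        return KinematicsSeries(
            t=self.t[mask], omega_y=self.omega_y[mask], alpha_y=self.alpha_y[mask]
        )


def mean_angular_velocity(sample: ClusterSample) -> Vec3:
    """Cluster angular velocity: component-wise mean over the four packages."""
    return sample.w.mean(axis=0)


def _rhs(a: np.ndarray, w_mean: np.ndarray, geom: ClusterGeometry) -> np.ndarray:
    """Right-hand side of the cluster system for one sample.

    Row i pairs package i's relative acceleration, stripped of the
    centripetal field, with the next arm vector (cyclically).
    """
    arms = (geom.r10, geom.r20, geom.r30)
    pair = (geom.r20, geom.r30, geom.r10)
    out = np.empty(3)
    for i in range(3):
        rel = a[i + 1] - a[0] - np.cross(w_mean, np.cross(w_mean, arms[i]))
        out[i] = rel @ pair[i]
    return out


def cluster_angular_acceleration(
    sample: ClusterSample, geom: ClusterGeometry
) -> Vec3:
    """Solve the rigid-body system for the angular acceleration vector.

    Exact inverse of :func:`rigid_body_forward_model` in the noise-free
    case.  The linear system is solved directly (no explicit matrix
    inverse); conditioning is validated once per geometry.
    """
    w_mean = mean_angular_velocity(sample)
    return np.linalg.solve(geom.matrix, _rhs(sample.a, w_mean, geom))


def solve_cluster_series(series: ClusterSeries, geom: ClusterGeometry) -> KinematicsSeries:
    """Vectorised cluster solution over a whole recording."""
    w_mean = series.w.mean(axis=1)                      # (N, 3)
    arms = np.stack([geom.r10, geom.r20, geom.r30])     # (3, 3)
    pair = np.stack([geom.r20, geom.r30, geom.r10])
    # centripetal field w x (w x r) per sample and arm
    wxr = np.cross(w_mean[:, None, :], arms[None, :, :])
    cent = np.cross(w_mean[:, None, :], wxr)
    rel = series.a[:, 1:4, :] - series.a[:, 0:1, :] - cent
    rhs = np.einsum("nij,ij->ni", rel, pair)            # (N, 3)
    alpha = np.linalg.solve(geom.matrix[None, :, :], rhs[..., None])[..., 0]
    return KinematicsSeries(
        t=series.t,
        omega_y=w_mean[:, 1],
        alpha_y=alpha[:, 1],
        omega=w_mean,
        alpha=alpha,
    )


def rigid_body_forward_model(
    alpha_true: Sequence[float],
    omega_true: Sequence[float],
    a0: Sequence[float],
    geom: ClusterGeometry,
    t: float = 0.0,
) -> ClusterSample:
    """Synthesise a cluster sample consistent with a rigid motion state.

    All four gyroscope readings are set to ``omega_true``; package
    accelerations follow a_i = a0 + alpha x r_i + w x (w x r_i).
    """
    alpha = _vec3(alpha_true, "alpha_true")
    omega = _vec3(omega_true, "omega_true")
    a_0 = _vec3(a0, "a0")
    arms = [np.zeros(3), geom.r10, geom.r20, geom.r30]
    a = np.stack(
        [a_0 + np.cross(alpha, r) + np.cross(omega, np.cross(omega, r)) for r in arms]
    )
    w = np.tile(omega, (4, 1))
    return ClusterSample(t=t, a=a, w=w)


def central_difference(values: Sequence[float], dt: float) -> np.ndarray:
    """Central difference quotient (f[i+1] - f[i-1]) / (2 dt).

    Boundary samples are unavailable and returned as NaN so that
    downstream extrema analysis drops them rather than seeing synthetic
    edge extrema.
    """
    f = np.asarray(values, dtype=float)
    if f.ndim != 1 or len(f) < 3:
        raise InsufficientDataError("central difference needs at least 3 samples")
    if dt <= 0:
        raise InvalidInputError("dt must be positive")
    out = np.full_like(f, np.nan)
    out[1:-1] = (f[2:] - f[:-2]) / (2.0 * dt)
    return out


def backward_difference(values: Sequence[float], dt: float) -> np.ndarray:
    """Backward difference quotient (f[i] - f[i-1]) / dt; first sample NaN."""
    f = np.asarray(values, dtype=float)
    if f.ndim != 1 or len(f) < 2:
        raise InsufficientDataError("backward difference needs at least 2 samples")
    if dt <= 0:
        raise InvalidInputError("dt must be positive")
    out = np.full_like(f, np.nan)
    out[1:] = np.diff(f) / dt
    return out


DifferenceMethod = Literal["central", "backward"]


def differentiate_omega(kin: KinematicsSeries, method: DifferenceMethod) -> KinematicsSeries:
    """Single-IMU view of a recording: alpha_y from differencing omega_y.

    Returns a new series on the trimmed grid where the quotient is
    defined.  This is the baseline a lone gyroscope supports, against
    which the cluster solution is compared.
    """
    if method == "central":
        alpha = central_difference(kin.omega_y, kin.dt)
        sl = slice(1, -1)
    elif method == "backward":
        alpha = backward_difference(kin.omega_y, kin.dt)
        sl = slice(1, None)
    else:
        raise InvalidInputError(f"unknown difference method {method!r}")
    return KinematicsSeries(
        t=kin.t[sl], omega_y=kin.omega_y[sl], alpha_y=alpha[sl]
    )


def lowpass(values: Sequence[float], dt: float, cutoff_hz: float = 20.0) -> np.ndarray:
    """Optional zero-phase low-pass smoothing stage (2nd-order Butterworth).

    Off by default throughout the framework; provided as a configurable
    noise-mitigation stage for raw cluster channels.
    """
    from scipy.signal import butter, filtfilt

    f = np.asarray(values, dtype=float)
    nyq = 0.5 / dt
    if cutoff_hz >= nyq:
        return f.copy()
    b, a = butter(2, cutoff_hz / nyq)
    return filtfilt(b, a, f)
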