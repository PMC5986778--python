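"""Two-degree-of-freedom orthogonal oscillator model.

A marker on a pole-like tree performing small free vibrations in the
horizontal plane is modelled as a particle restrained by two orthogonal
spring/damper pairs.  Along the principal (stiffness) axes ``X`` and ``Y``
the equations of motion decouple into two damped linear oscillators::

    X'' + 2*delta1*X' + omega1**2 * X = 0
    Y'' + 2*delta2*Y' + omega2**2 * Y = 0

with natural frequencies ``omega1, omega2`` (rad/s) and exponential decay
constants ``delta1, delta2`` (1/s).  The principal axes sit at an angle
``alpha`` to the measurement x-axis.  This module holds the parameter
containers, the closed-form underdamped solutions for a pull-and-release
start (release from rest at a nonzero displacement), and the rotation
between measurement and principal coordinates.

Naming note: ``delta`` (units 1/s) is the envelope decay rate, sometimes
called the viscous damping ratio in the tree-sway literature; the
dimensionless ``zeta = delta/omega`` is the conventional damping ratio,
here called the damping factor.  Both names are kept in docstrings to
bridge the two conventions.

Units are fixed throughout the package: mm, s, rad/s.  Angles are radians
internally; user-facing reports convert to degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import OverdampedError, ParameterError

__all__ = [
    "OscillatorParameters",
    "DampedFrequencies",
    "PlanarTrajectory",
    "RectangleEnvelope",
    "damped_frequency",
    "damping_factor",
    "principal_displacement",
    "to_principal",
    "from_principal",
    "rectangle_envelope",
]


def damped_frequency(omega: float, delta: float) -> float:
    """Damped angular frequency ``sqrt(omega**2 - delta**2)``.

    Parameters
    ----------
    omega : float
        Undamped natural angular frequency, rad/s.
    delta : float
        Exponential decay constant, 1/s.  Must satisfy ``0 <= delta < omega``
        (underdamped motion); otherwise the model is not oscillatory and
        :class:`~treesway.errors.OverdampedError` is raised.
    """
    if omega <= 0:
        raise ParameterError(f"omega must be positive, got {omega}")
    if delta < 0:
        raise ParameterError(f"delta must be non-negative, got {delta}")
    if delta >= omega:
        raise OverdampedError(
            f"delta={delta} >= omega={omega}: motion would be overdamped; "
            "the orthogonal-oscillation model assumes oscillatory decay"
        )
    return math.sqrt(omega * omega - delta * delta)


def damping_factor(delta: float, omega: float) -> float:
    """Dimensionless damping factor ``zeta = delta/omega``.

    ``zeta`` is the conventional (dimensionless) damping ratio; it lies in
    ``[0, 1)`` for underdamped motion.
    """
    if omega <= 0:
        raise ParameterError(f"omega must be positive, got {omega}")
    if delta < 0:
        raise ParameterError(f"delta must be non-negative, got {delta}")
    return delta / omega


@dataclass(frozen=True)
class OscillatorParameters:
    """Parameters of the two orthogonal damped oscillators.

    Attributes
    ----------
    omega1, omega2 : float
        Natural angular frequencies along the principal X and Y axes, rad/s.
    delta1, delta2 : float
        Decay constants along X and Y, 1/s; ``0 <= delta_i < omega_i``.
    alpha : float
        Angle from the measurement x-axis to the principal X-axis, radians.
    X0, Y0 : float
        Initial displacements along the principal axes, mm (release from
        rest, so these are also the rectangle envelope half-sides).
    """

    omega1: float
    omega2: float
    delta1: float = 0.0
    delta2: float = 0.0
    alpha: float = 0.0
    X0: float = 1.0
    Y0: float = 1.0

    def __post_init__(self) -> None:
        # damped_frequency validates omega > 0 and 0 <= delta < omega
        damped_frequency(self.omega1, self.delta1)
        damped_frequency(self.omega2, self.delta2)
        if not all(
            math.isfinite(v)
            for v in (self.alpha, self.X0, self.Y0)
        ):
            raise ParameterError("alpha, X0, Y0 must be finite")

    @property
    def omega_bar1(self) -> float:
        return damped_frequency(self.omega1, self.delta1)

    @property
    def omega_bar2(self) -> float:
        return damped_frequency(self.omega2, self.delta2)

    @property
    def damped_frequencies(self) -> "DampedFrequencies":
        return DampedFrequencies(self.omega_bar1, self.omega_bar2)

    @property
    def zeta1(self) -> float:
        return damping_factor(self.delta1, self.omega1)

    @property
    def zeta2(self) -> float:
        return damping_factor(self.delta2, self.omega2)

    def canonical(self) -> "OscillatorParameters":
        """Return the equivalent parameter set with ``omega1 <= omega2``.

        The axis pair is only defined modulo a 90 degree relabelling that
        swaps (omega1, delta1) with (omega2, delta2).  The canonical form
        labels the lower-frequency axis X and reports alpha, the
        measurement-frame angle of that axis, reduced to [0, pi).
        """
        p = self
        if p.omega1 > p.omega2:
            p = replace(
                p,
                omega1=p.omega2,
                omega2=p.omega1,
                delta1=p.delta2,
                delta2=p.delta1,
                alpha=p.alpha + math.pi / 2,
                X0=p.Y0,
                Y0=-p.X0,
            )
        return replace(p, alpha=p.alpha % math.pi)


@dataclass(frozen=True)
class DampedFrequencies:
    """Damped angular frequencies ``omega_bar_i = sqrt(omega_i^2 - delta_i^2)``."""

    omega_bar1: float
    omega_bar2: float


def principal_displacement(
    params: OscillatorParameters, axis: str, t
):
    """Closed-form underdamped displacement along one principal axis.

    For a release from rest at displacement ``A0`` the solution is::

        A0 * exp(-delta*t) * (cos(omega_bar*t) + (delta/omega_bar)*sin(omega_bar*t))

    which has zero velocity at ``t = 0`` and reduces to ``A0*cos(omega*t)``
    when ``delta = 0``.

    Parameters
    ----------
    params : OscillatorParameters
    axis : {'X', 'Y'}
        Which principal coordinate to evaluate.
    t : float or array_like
        Time(s) in seconds, ``t >= 0``.
    """
    if axis == "X":
        a0, delta, wbar = params.X0, params.delta1, params.omega_bar1
    elif axis == "Y":
        a0, delta, wbar = params.Y0, params.delta2, params.omega_bar2
    else:
        raise ParameterError(f"axis must be 'X' or 'Y', got {axis!r}")
    t = np.asarray(t, dtype=float)
    out = a0 * np.exp(-delta * t) * (
        np.cos(wbar * t) + (delta / wbar) * np.sin(wbar * t)
    )
    return out if out.ndim else float(out)


def free_decay(t, amplitude0: float, delta: float, omega_bar: float):
    """Damped-cosine release-from-rest waveform used by the axis fits.

    Same closed form as :func:`principal_displacement`, parameterised
    directly by (A0, delta, omega_bar) for fitting.
    """
    t = np.asarray(t, dtype=float)
    return amplitude0 * np.exp(-delta * t) * (
        np.cos(omega_bar * t) + (delta / omega_bar) * np.sin(omega_bar * t)
    )


def to_principal(x, y, alpha: float):
    """Rotate measurement-frame coordinates into the principal frame.

    ``X = x*cos(alpha) + y*sin(alpha);  Y = -x*sin(alpha) + y*cos(alpha)``.
    Norm preserving.
    """
    c, s = math.cos(alpha), math.sin(alpha)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return x * c + y * s, -x * s + y * c


def from_principal(X, Y, alpha: float):
    """Inverse of :func:`to_principal` (rotation by ``-alpha``)."""
    return to_principal(X, Y, -alpha)


@dataclass(frozen=True)
class PlanarTrajectory:
    """Uniformly sampled planar marker track in the measurement frame.

    ``times`` in s (strictly increasing, uniform step), ``x``/``y`` in mm.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sample_rate: float
    marker_id: str = "marker"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if not (t.shape == x.shape == y.shape) or t.ndim != 1 or t.size < 2:
            raise ParameterError(
                "times, x, y must be equal-length 1-D arrays with >= 2 samples"
            )
        if not (
            np.all(np.isfinite(t)) and np.all(np.isfinite(x)) and np.all(np.isfinite(y))
        ):
            raise ParameterError("trajectory contains non-finite values")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise ParameterError("times must be strictly increasing")
        step = float(np.median(steps))
        if np.max(np.abs(steps - step)) > 1e-6 * step:
            raise ParameterError("times must be uniformly spaced")
        if abs(step * self.sample_rate - 1.0) > 1e-6:
            raise ParameterError(
                f"sample_rate={self.sample_rate} inconsistent with time step {step}"
            )

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def points(self) -> np.ndarray:
        """N x 2 array of (x, y) samples, mm."""
        return np.column_stack([self.x, self.y])


@dataclass(frozen=True)
class RectangleEnvelope:
    """Bounding rectangle of undamped corner-start motion.

    Sides are parallel to the principal axes; ``corners`` are the
    measurement-frame images of (+-X0, +-Y0) and ``half_diagonal`` is
    ``A = sqrt(X0**2 + Y0**2)``, the release displacement.
    """

    corners: np.ndarray = field(repr=False)
    half_diagonal: float


def rectangle_envelope(params: OscillatorParameters) -> RectangleEnvelope:
    """Envelope rectangle of the trajectory for the given parameters."""
    X0, Y0 = params.X0, params.Y0
    pts = np.array(
        [[X0, Y0], [-X0, Y0], [-X0, -Y0], [X0, -Y0]], dtype=float
    )
    xs, ys = from_principal(pts[:, 0], pts[:, 1], params.alpha)
    return RectangleEnvelope(
        corners=np.column_stack([xs, ys]),
        half_diagonal=math.hypot(X0, Y0),
    )
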