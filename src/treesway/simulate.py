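"""Synthetic pull-and-release trajectory generator and the shape atlas.

The generator emulates the experimental protocol used for tree-sway
recordings: the stem is pulled to a static deflection, held at rest, then
released, so the motion is free damped biaxial oscillation starting from
rest at a nonzero displacement.  In the principal frame the release point
``(X0, Y0)`` is a corner of the envelope rectangle; the measured
coordinates are the principal solutions rotated by the principal-axis
angle ``alpha``, optionally corrupted by i.i.d. Gaussian marker noise.

The shape atlas reproduces the qualitative classification of trajectory
shapes on a grid of frequency gaps ``p`` (percentage difference between
the two natural frequencies, ``omega2 = omega1*(1 + p/100)``) and decay
constants ``delta``: trajectories become narrower as ``p`` decreases and
as damping increases.  The ``narrowness`` statistic makes that visual
judgement quantitative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .core import (
    OscillatorParameters,
    PlanarTrajectory,
    from_principal,
    principal_displacement,
)
from .errors import ParameterError, SamplingError

__all__ = [
    "SimulationSpec",
    "generate_trajectory",
    "from_percentage",
    "narrowness",
    "shape_atlas",
    "atlas_narrowness",
    "ATLAS_OMEGA1",
    "ATLAS_P_VALUES",
    "ATLAS_DELTA_VALUES",
]

#: Default shape-atlas grid: base frequency 20 rad/s, frequency gaps of
#: 1/3/5 % and decay constants 0.1/0.3/0.5 1/s on both axes.
ATLAS_OMEGA1 = 20.0
ATLAS_P_VALUES = (1.0, 3.0, 5.0)
ATLAS_DELTA_VALUES = (0.1, 0.3, 0.5)


def from_percentage(omega1: float, p: float) -> float:
    """Second natural frequency from a percentage gap: ``omega1*(1 + p/100)``."""
    if omega1 <= 0:
        raise ParameterError(f"omega1 must be positive, got {omega1}")
    if p < 0:
        raise ParameterError(f"p must be non-negative, got {p}")
    return omega1 * (1.0 + p / 100.0)


@dataclass(frozen=True)
class SimulationSpec:
    """Specification of one synthetic pull-and-release recording.

    ``noise_sd`` is the standard deviation (mm) of additive Gaussian noise
    applied independently to each coordinate of each sample in the
    measurement frame, emulating marker-tracking error.
    """

    params: OscillatorParameters
    duration: float = 30.0
    sample_rate: float = 100.0
    noise_sd: float = 0.0
    seed: int = 0
    marker_id: str = "sim"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ParameterError(f"duration must be positive, got {self.duration}")
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        f_max = max(self.params.omega1, self.params.omega2) / (2.0 * math.pi)
        if self.sample_rate <= 2.0 * f_max:
            raise SamplingError(
                f"sample_rate={self.sample_rate} Hz is at or below the Nyquist "
                f"rate {2 * f_max:.3f} Hz for omega_max="
                f"{max(self.params.omega1, self.params.omega2):.3f} rad/s; "
                "use a faster rate (>= 10x the oscillation frequency is typical "
                "for motion capture)"
            )


def generate_trajectory(spec: SimulationSpec) -> PlanarTrajectory:
    """Simulate one marker track for the given specification.

    The principal solutions are evaluated on the uniform time grid and
    rotated into the measurement frame; the motion starts from rest at the
    rotated image of ``(X0, Y0)``.  Identical seeds give bitwise-identical
    output; ``noise_sd = 0`` gives a noiseless record.
    """
    n = int(round(spec.duration * spec.sample_rate)) + 1
    times = np.arange(n, dtype=float) / spec.sample_rate
    X = principal_displacement(spec.params, "X", times)
    Y = principal_displacement(spec.params, "Y", times)
    x, y = from_principal(X, Y, spec.params.alpha)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        x = x + rng.normal(0.0, spec.noise_sd, size=n)
        y = y + rng.normal(0.0, spec.noise_sd, size=n)
    return PlanarTrajectory(
        times=times, x=x, y=y, sample_rate=spec.sample_rate, marker_id=spec.marker_id
    )


def narrowness(traj: PlanarTrajectory | np.ndarray) -> float:
    """Minor-to-major axis ratio of the trajectory's point cloud, in [0, 1].

    Computed as the ratio of the smaller to the larger singular value of
    the mean-centered (x, y) sample matrix: 0 for collinear points, 1 for
    an isotropic cloud.  Invariant to rotation and uniform scaling, so it
    depends only on the shape of the trajectory, not its orientation or
    amplitude.
    """
    pts = traj.points() if isinstance(traj, PlanarTrajectory) else np.asarray(traj, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 10:
        raise ParameterError("narrowness needs an (n >= 10) x 2 point cloud")
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[0] <= 0:
        raise ParameterError("degenerate point cloud: all points identical")
    return float(s[1] / s[0])


def shape_atlas(
    omega1: float = ATLAS_OMEGA1,
    p_values=ATLAS_P_VALUES,
    delta_values=ATLAS_DELTA_VALUES,
    duration: float = 20.0,
    sample_rate: float = 200.0,
    alpha: float = 0.0,
) -> dict[tuple[float, float], PlanarTrajectory]:
    """Grid of noiseless corner-start trajectories indexed by ``(p, delta)``.

    Each cell uses ``omega2 = omega1*(1 + p/100)`` and equal decay
    ``delta1 = delta2 = delta``.  The release point is the rectangle corner
    ``X0 = Y0 = 1`` mm; the shapes are scale-free so a unit amplitude loses
    no generality.
    """
    p_values = list(p_values)
    delta_values = list(delta_values)
    if not p_values or not delta_values:
        raise ParameterError("p_values and delta_values must be non-empty")
    grid: dict[tuple[float, float], PlanarTrajectory] = {}
    for p in p_values:
        for delta in delta_values:
            params = OscillatorParameters(
                omega1=omega1,
                omega2=from_percentage(omega1, p),
                delta1=delta,
                delta2=delta,
                alpha=alpha,
                X0=1.0,
                Y0=1.0,
            )
            spec = SimulationSpec(
                params=params,
                duration=duration,
                sample_rate=sample_rate,
                noise_sd=0.0,
                marker_id=f"p{p:g}_d{delta:g}",
            )
            grid[(p, delta)] = generate_trajectory(spec)
    return grid


def atlas_narrowness(grid: dict[tuple[float, float], PlanarTrajectory]) -> dict:
    """Narrowness statistic for each cell of a shape-atlas grid."""
    return {key: narrowness(traj) for key, traj in grid.items()}
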