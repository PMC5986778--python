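"""Geometric identification of the coincidence time t1 and the principal axes.

For two close natural frequencies the two principal oscillations drift
apart by half a period over the coincidence time ``t1 = pi/(wbar2 - wbar1)``,
at which instant both velocities are (approximately) simultaneously zero
and the particle sits on a diagonal of the envelope rectangle.  ``t1`` is
found from the data alone: the extrema of the recorded x(t) and y(t) are
paired in time, and the signed time differences between paired extrema,
plotted against time, cross zero at ``t1``.

Knowing ``t1``, the release point ``A = (x(0), y(0))`` and the decayed
position ``B = (x(t1), y(t1))`` give the rectangle construction: ``B`` is
rescaled by ``lambda = |OA|/|OB|`` onto the opposite diagonal corner ``C``
(equal diagonals), and the chord ``CA`` is parallel to one principal axis
-- the X axis if the number of y half-periods before t1 is even, the Y
axis if it is odd.  The angle of ``CA`` therefore yields the
principal-axis angle ``alpha``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import CoincidenceError, ExtremaError, GeometryError, ParameterError

__all__ = [
    "ExtremaSequence",
    "TimeDifferenceSeries",
    "T1Estimate",
    "find_extrema",
    "pair_differences",
    "estimate_t1",
    "frequency_gap",
    "estimate_lambda",
    "estimate_alpha",
]


@dataclass(frozen=True)
class ExtremaSequence:
    """Sub-sample interpolated extremum times of one recorded coordinate."""

    coordinate: str
    times: np.ndarray
    values: np.ndarray
    kinds: np.ndarray  # '+' for maxima, '-' for minima

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class TimeDifferenceSeries:
    """Signed time differences between paired x- and y-extrema.

    ``deltas[i] = t_x_extremum - t_y_extremum`` for the i-th pair;
    ``ref_times[i]`` is the midpoint of the pair.
    """

    ref_times: np.ndarray
    deltas: np.ndarray

    def __len__(self) -> int:
        return self.ref_times.size


@dataclass(frozen=True)
class T1Estimate:
    """Coincidence time and the half-period count used for parity."""

    t1: float
    n_half_periods: int
    crossing_index: int
    #: 'strict' when both differences bracketing the zero were small;
    #: 'fallback' when the cleanest available sign change was used instead
    #: (heavy unequal damping can displace the zero near t1).
    quality: str = "strict"


def _refine_quadratic(t: np.ndarray, v: np.ndarray, idx: int):
    """Sub-sample extremum (time, value) via a parabola through 3 samples."""
    if idx == 0 or idx == v.size - 1:
        return float(t[idx]), float(v[idx])
    y0, y1, y2 = v[idx - 1], v[idx], v[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        return float(t[idx]), float(v[idx])
    shift = 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -0.5, 0.5))
    h = float(t[idx + 1] - t[idx])
    value = y1 - 0.25 * (y0 - y2) * shift
    return float(t[idx]) + shift * h, float(value)


def find_extrema(
    times,
    values,
    min_prominence_fraction: float = 0.05,
    coordinate: str = "signal",
) -> ExtremaSequence:
    """Locate local extrema of a sampled coordinate with sub-sample timing.

    Maxima and minima with topographic prominence of at least
    ``min_prominence_fraction * max|signal|`` are kept; each extremum time
    is refined by quadratic interpolation through the three samples around
    the discrete peak.  Runs of same-kind extrema (possible when shallow
    counter-extrema fall below the prominence floor) are collapsed to the
    most extreme member so that kinds strictly alternate.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size != v.size or t.size < 5:
        raise ParameterError("need >= 5 samples of equal-length times/values")
    if not 0.0 < min_prominence_fraction < 1.0:
        raise ParameterError(
            f"min_prominence_fraction must be in (0, 1), got {min_prominence_fraction}"
        )
    scale = float(np.max(np.abs(v)))
    if scale == 0.0:
        raise ExtremaError(f"{coordinate}: signal is identically zero")
    prominence = min_prominence_fraction * scale
    imax, _ = find_peaks(v, prominence=prominence)
    imin, _ = find_peaks(-v, prominence=prominence)
    if imax.size + imin.size == 0:
        raise ExtremaError(
            f"{coordinate}: no extrema with prominence >= "
            f"{min_prominence_fraction:g} x max|signal|; record may be too "
            "short, constant, or the threshold too high"
        )
    idx = np.concatenate([imax, imin])
    kind = np.concatenate([np.full(imax.size, "+"), np.full(imin.size, "-")])
    order = np.argsort(idx)
    idx, kind = idx[order], kind[order]

    # collapse runs of equal kind, keeping the most extreme member
    keep_idx: list[int] = []
    keep_kind: list[str] = []
    for i, k in zip(idx, kind):
        i = int(i)
        if keep_kind and keep_kind[-1] == k:
            prev = keep_idx[-1]
            if (v[i] > v[prev]) if k == "+" else (v[i] < v[prev]):
                keep_idx[-1] = i
        else:
            keep_idx.append(i)
            keep_kind.append(str(k))

    refined = [_refine_quadratic(t, v, i) for i in keep_idx]
    return ExtremaSequence(
        coordinate=coordinate,
        times=np.array([r[0] for r in refined]),
        values=np.array([r[1] for r in refined]),
        kinds=np.array(keep_kind),
    )


def pair_differences(
    ex_x: ExtremaSequence, ex_y: ExtremaSequence
) -> TimeDifferenceSeries:
    """Pair each y-extremum with its nearest x-extremum and form signed gaps.

    Pairing is one-to-one greedy nearest-neighbour: candidate pairs are
    taken in order of increasing |time gap| and accepted while both members
    are unused.  The signed difference is ``t_x - t_y``; the reference time
    of a pair is its midpoint.
    """
    if len(ex_x) == 0 or len(ex_y) == 0:
        raise ParameterError("both extrema sequences must be non-empty")
    tx, ty = ex_x.times, ex_y.times
    # candidate pairs: for each y-extremum the two bracketing x-extrema
    pos = np.searchsorted(tx, ty)
    cand: list[tuple[float, int, int]] = []
    for j, p in enumerate(pos):
        for i in (p - 1, p):
            if 0 <= i < tx.size:
                cand.append((abs(tx[i] - ty[j]), i, j))
    cand.sort()
    used_x: set[int] = set()
    used_y: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in cand:
        if i in used_x or j in used_y:
            continue
        used_x.add(i)
        used_y.add(j)
        pairs.append((i, j))
    if len(pairs) < 2:
        raise CoincidenceError("fewer than 2 extremum pairs; record too short")
    pairs.sort(key=lambda ij: ty[ij[1]])
    deltas = np.array([tx[i] - ty[j] for i, j in pairs])
    ref = np.array([0.5 * (tx[i] + ty[j]) for i, j in pairs])
    return TimeDifferenceSeries(ref_times=ref, deltas=deltas)


def estimate_t1(
    diffs: TimeDifferenceSeries,
    max_crossing_fraction: float = 0.25,
    y_extrema_times=None,
) -> T1Estimate:
    """Coincidence time from the first genuine zero of the time-difference series.

    The paired-difference series is a sawtooth: as the faster oscillation
    gains half a period on the slower one, the nearest-neighbour pairing
    re-wraps, producing a large jump of about one half-period that is not a
    coincidence.  A sign change is accepted as genuine only when both
    bracketing differences are small (below ``max_crossing_fraction`` of
    the median extremum spacing); ``t1`` is then the linear interpolant of
    the zero.  Later coincidences (near 2*t1, ...) are ignored: the first
    crossing is least distorted by amplitude decay.

    ``n_half_periods`` counts the y-extrema before ``t1`` -- the
    half-period count whose parity selects which corner is reached.  Pass
    ``y_extrema_times`` to count from the full (interpolated) extrema
    sequence; otherwise paired differences are counted, which can miss the
    occasional unpaired extremum near a pairing wrap.
    """
    ref, d = diffs.ref_times, diffs.deltas
    if len(diffs) < 2:
        raise CoincidenceError("need at least 2 paired differences")
    spacing = float(np.median(np.diff(ref))) if len(diffs) > 2 else float(ref[1] - ref[0])
    tol = max_crossing_fraction * spacing
    if float(np.max(np.abs(d))) < 0.01 * spacing:
        raise CoincidenceError(
            "extrema time differences never grow: the two damped frequencies "
            "are equal or too close for the record length (no lateral drift)"
        )

    def _result(t1: float, i: int, quality: str) -> T1Estimate:
        if y_extrema_times is not None:
            n = int(np.count_nonzero(np.asarray(y_extrema_times, float) < t1))
        else:
            n = i + 1  # pairs are y-ordered
        return T1Estimate(t1=t1, n_half_periods=n, crossing_index=i, quality=quality)

    crossings = []  # (max(|a|,|b|), i)
    for i in range(len(d) - 1):
        a, b = d[i], d[i + 1]
        if (a == 0.0 and ref[i] > 0) or a * b < 0.0:
            crossings.append((max(abs(a), abs(b)), i))
    for size, i in crossings:
        if size <= tol:
            a, b = d[i], d[i + 1]
            if a == 0.0:
                return _result(float(ref[i]), i, "strict")
            t1 = float(ref[i] - a * (ref[i + 1] - ref[i]) / (b - a))
            return _result(t1, i, "strict")
    # No crossing with small bracketing differences.  Heavy unequal damping
    # can push one coordinate through a beat node near t1, displacing the
    # zero; fall back to the cleanest sign change rather than failing.
    acceptable = [c for c in crossings if c[0] <= 0.45 * spacing]
    if acceptable:
        _, i = min(acceptable)
        a, b = d[i], d[i + 1]
        t1 = float(ref[i]) if a == 0.0 else float(
            ref[i] - a * (ref[i + 1] - ref[i]) / (b - a)
        )
        return _result(t1, i, "fallback")
    raise CoincidenceError(
        "no zero crossing in the extrema time-difference series: the two "
        "damped frequencies are too close (or equal) for the record length, "
        "or the motion is effectively one-dimensional"
    )


def frequency_gap(t1: float) -> float:
    """Damped-frequency difference implied by t1: ``wbar2 - wbar1 = pi/t1``."""
    if t1 <= 0:
        raise ParameterError(f"t1 must be positive, got {t1}")
    return math.pi / t1


def estimate_lambda(x0: float, y0: float, xt1: float, yt1: float) -> float:
    """Diagonal rescaling factor ``lambda = |OA| / |OB|``.

    ``A = (x0, y0)`` is the release point, ``B = (x(t1), y(t1))`` the
    decayed position at the coincidence time; equality of the rectangle
    diagonals maps B onto the corner ``C = lambda*B``.
    """
    ob = math.hypot(xt1, yt1)
    if ob == 0.0:
        raise GeometryError("position at t1 is the origin; lambda undefined")
    return math.hypot(x0, y0) / ob


def estimate_alpha(
    x0: float,
    y0: float,
    xt1: float,
    yt1: float,
    n_parity: str,
) -> float:
    """Principal-axis angle from the rectangle-diagonal construction, rad.

    With ``C = lambda*(xt1, yt1)`` and ``A = (x0, y0)``, the chord
    ``CA = A - C`` is parallel to the principal X axis when the y
    half-period count before t1 is even, and to the Y axis when odd.  The
    quadrant is resolved with the two-argument arctangent and the result
    reduced to [0, pi) (principal directions are unsigned).
    """
    if n_parity not in ("even", "odd"):
        raise ParameterError(f"n_parity must be 'even' or 'odd', got {n_parity!r}")
    oa = math.hypot(x0, y0)
    if oa == 0.0:
        raise GeometryError("release point at the origin; alpha undefined")
    lam = estimate_lambda(x0, y0, xt1, yt1)
    ca_x = x0 - lam * xt1
    ca_y = y0 - lam * yt1
    if math.hypot(ca_x, ca_y) < 1e-9 * oa:
        raise GeometryError(
            "chord CA is numerically zero; principal-axis angle indeterminate"
        )
    angle = math.atan2(ca_y, ca_x)
    if n_parity == "odd":
        angle -= math.pi / 2.0  # CA parallel to the Y principal axis
    return angle % math.pi
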