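"""Cumulative winding number of the flattened curve, and integer crossings.

For a discrete plane curve φ(t) = (x(t), y(t)) the cumulative winding
number accumulates, in revolutions, the signed angle between rays from the
origin to consecutive points:

    W(0) = 0
    W(t) = W(t−1) + (1/2π) atan2(y(t)x(t−1) − x(t)y(t−1),
                                 x(t)x(t−1) + y(t)y(t−1))

The two-argument arctangent gives the signed angle in (−π, π] and is
robust in all quadrants.  In a coiling (solenoid) region W grows linearly
with slope 1/period; residues where W crosses successive integers delimit
repeat units.

Because the initial normal frame's handedness is an arbitrary choice, the
raw sign of W is arbitrary too; :meth:`WindingProfile.oriented` flips a
downward-trending profile to positive and records the handedness so that
annotations do not depend on the frame choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, ValidationError
from .geometry import FlatCurve

#: Points of the flattened curve closer to the origin than this (Å) make
#: the winding angle unstable and raise instead.
ORIGIN_GUARD = 1e-9


@dataclass(frozen=True)
class WindingProfile:
    """Cumulative winding number W(t) per residue, in revolutions."""

    values: np.ndarray
    flat: FlatCurve | None = None
    handedness: int = 1

    def __len__(self) -> int:
        return len(self.values)

    def oriented(self) -> "WindingProfile":
        """Return a profile with non-negative net winding.

        If W(n) < 0 the whole profile is negated and the handedness flag
        flipped; otherwise self is returned unchanged.
        """
        if self.values[-1] < 0:
            return WindingProfile(
                values=-self.values, flat=self.flat, handedness=-self.handedness
            )
        return self


def cumulative_winding(flat: FlatCurve | np.ndarray) -> WindingProfile:
    """Discrete cumulative winding number of a plane curve about the origin.

    Raises
    ------
    DegenerateGeometryError
        If any point lies within :data:`ORIGIN_GUARD` of the origin.
    """
    if not isinstance(flat, FlatCurve):
        flat = FlatCurve(points=np.asarray(flat, dtype=float))
    pts = flat.points
    if len(pts) < 2:
        raise ValidationError("flat curve must have length >= 2")
    r = np.hypot(pts[:, 0], pts[:, 1])
    bad = np.nonzero(r <= ORIGIN_GUARD)[0]
    if len(bad):
        raise DegenerateGeometryError(
            "flattened point at the origin", index=int(bad[0])
        )
    x, y = pts[:, 0], pts[:, 1]
    cross = x[:-1] * y[1:] - y[:-1] * x[1:]
    dot = x[:-1] * x[1:] + y[:-1] * y[1:]
    steps = np.arctan2(cross, dot) / (2.0 * np.pi)
    values = np.concatenate([[0.0], np.cumsum(steps)])
    return WindingProfile(values=values, flat=flat)


def integer_crossings(
    profile: WindingProfile | np.ndarray,
    span: tuple[int, int] | None = None,
    offset: float = 0.0,
) -> np.ndarray:
    """Indices where W − offset steps across an integer.

    A crossing is reported at ``t`` (the first index at or past the
    crossing) whenever W(t−1) − offset and W(t) − offset straddle an
    integer: there is an integer k with W(t−1) − offset < k <= W(t) −
    offset, or symmetrically for a decreasing step.  ``span`` is a
    half-open interval [a, b) of indices; by default the whole profile.
    """
    values = profile.values if isinstance(profile, WindingProfile) else np.asarray(profile)
    n = len(values)
    if span is None:
        span = (0, n)
    a, b = int(span[0]), int(span[1])
    if not (0 <= a < b <= n):
        raise ValidationError(f"span {span} outside profile of length {n}")
    if b - a < 2:
        return np.array([], dtype=int)
    x = values[a:b] - offset
    prev, cur = x[:-1], x[1:]
    up = cur >= np.floor(prev) + 1.0
    down = cur <= np.ceil(prev) - 1.0
    return a + 1 + np.nonzero(up | down)[0]


def crossing_count(values: np.ndarray, a: int, b: int, offset: float) -> int:
    """Closed-form crossing count for a monotone increasing profile."""
    lo = values[a] - offset
    hi = values[b - 1] - offset
    return int(math.floor(hi) - math.floor(lo))
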