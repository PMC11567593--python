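"""Backbone smoothing, tangents, parallel-transported frames, flattening.

The α-carbon trace γ(t) is smoothed into a "backbone" γ_σ by per-channel
convolution with a Gaussian of width σ (in residue units; default 20).
Tangents γ'_σ come from the derivative-of-Gaussian kernel.  A 2D
orthonormal frame for the plane normal to the tangent is propagated along
the backbone by orthogonal projection followed by the orthogonal-Procrustes
re-orthonormalization (SVD with singular values replaced by ones); this is
discrete parallel transport, i.e. the frame rotates as little as possible
from one residue to the next.  The flattened curve

    φ(t) = A(t)ᵀ (γ(t) − γ_σ(t))

records the position of the chain in the moving normal plane, and is the
input to the winding-number computation.

Numerical conventions
---------------------
* Kernels are truncated at ±4σ.  The smoothing kernel is renormalized to
  unit sum at every output position (edge-aware), so constant curves are
  preserved exactly and termini are not shrunk toward zero.
* The derivative kernel is corrected to zero sum and scaled to map the unit
  ramp to exactly 1; near the boundary the curve is extended by odd
  reflection, which keeps linear curves exact everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError, ValidationError

DEFAULT_SIGMA = 20.0
KERNEL_TRUNCATION_SIGMAS = 4.0


@dataclass(frozen=True)
class BackboneCurve:
    """Smoothed backbone γ_σ(t) and its tangents γ'_σ(t)."""

    points: np.ndarray  # (n, 3)
    tangents: np.ndarray  # (n, 3)
    sigma: float

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class FrameField:
    """Per-residue 3×2 orthonormal bases A(t) of the normal planes."""

    frames: np.ndarray  # (n, 3, 2)

    def __len__(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class FlatCurve:
    """The flattened 2D curve φ(t), in Å."""

    points: np.ndarray  # (n, 2)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValidationError("FlatCurve points must be (n, 2)")
        if not np.all(np.isfinite(pts)):
            raise ValidationError("FlatCurve points must be finite")

    def __len__(self) -> int:
        return len(self.points)


def _check_curve(curve: np.ndarray) -> np.ndarray:
    curve = np.asarray(curve, dtype=float)
    if curve.ndim == 1:
        curve = curve[:, None]
    if len(curve) < 2:
        raise ValidationError("curve must have length >= 2")
    if not np.all(np.isfinite(curve)):
        raise ValidationError("curve contains non-finite values")
    return curve


def _gaussian_kernel(sigma: float, truncation: float) -> np.ndarray:
    radius = max(1, int(np.ceil(truncation * sigma)))
    t = np.arange(-radius, radius + 1, dtype=float)
    return np.exp(-(t**2) / (2.0 * sigma**2))


def gaussian_smooth(
    curve: np.ndarray,
    sigma: float,
    truncation: float = KERNEL_TRUNCATION_SIGMAS,
) -> np.ndarray:
    """Convolve each coordinate channel with a truncated Gaussian.

    The kernel is renormalized to unit sum per output position, so the part
    of the kernel hanging off the ends of the curve is redistributed and
    constants are preserved exactly at the boundary.
    """
    curve = _check_curve(curve)
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    kernel = _gaussian_kernel(sigma, truncation)
    n = len(curve)
    radius = (len(kernel) - 1) // 2
    # 'full' + slice rather than 'same': numpy's 'same' follows the longer
    # array, which breaks for curves shorter than the kernel support.
    weight = np.convolve(np.ones(n), kernel, mode="full")[radius : radius + n]
    out = np.empty_like(curve)
    for c in range(curve.shape[1]):
        conv = np.convolve(curve[:, c], kernel, mode="full")[radius : radius + n]
        out[:, c] = conv / weight
    return out


def gaussian_tangent(
    curve: np.ndarray,
    sigma: float,
    truncation: float = KERNEL_TRUNCATION_SIGMAS,
) -> np.ndarray:
    """Tangent vectors via the derivative-of-Gaussian kernel.

    The discrete kernel is corrected to have exactly zero sum and to map
    the ramp (…,−1,0,1,…) to 1, so linear curves yield exact unit slope.
    The curve is extended by odd reflection at both ends before the
    convolution, which keeps tangents of linear curves exact at the
    boundary as well.
    """
    curve = _check_curve(curve)
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    radius = max(1, int(np.ceil(truncation * sigma)))
    t = np.arange(-radius, radius + 1, dtype=float)
    kernel = -t * np.exp(-(t**2) / (2.0 * sigma**2))
    kernel -= kernel.mean()  # exact zero sum
    # (k ⋆ ramp)(0) = -Σ s k(s); scale so it equals 1
    scale = -(t * kernel).sum()
    kernel /= scale

    n = len(curve)
    pad = min(radius, n - 1)
    out = np.empty_like(curve)
    for c in range(curve.shape[1]):
        x = curve[:, c]
        ext = np.concatenate(
            [2 * x[0] - x[pad:0:-1], x, 2 * x[-1] - x[-2 : -2 - pad : -1]]
        )
        full = np.convolve(ext, kernel, mode="full")
        out[:, c] = full[radius + pad : radius + pad + n]
    return out


def smooth_backbone(
    curve: np.ndarray,
    sigma: float = DEFAULT_SIGMA,
    truncation: float = KERNEL_TRUNCATION_SIGMAS,
) -> BackboneCurve:
    """Convenience wrapper producing points and tangents in one object."""
    return BackboneCurve(
        points=gaussian_smooth(curve, sigma, truncation),
        tangents=gaussian_tangent(curve, sigma, truncation),
        sigma=sigma,
    )


def _initial_frame(tangent: np.ndarray) -> np.ndarray:
    """Deterministic orthonormal completion of the initial tangent.

    Takes the standard basis vector least aligned with the tangent,
    Gram-Schmidts it against the tangent for the first column, and uses
    tangent × column1 (normalized) for the second.
    """
    u = tangent / np.linalg.norm(tangent)
    e = np.zeros(3)
    e[int(np.argmin(np.abs(u)))] = 1.0
    c1 = e - (e @ u) * u
    c1 /= np.linalg.norm(c1)
    c2 = np.cross(u, c1)
    c2 /= np.linalg.norm(c2)
    return np.column_stack([c1, c2])


def parallel_transport_frames(tangents: np.ndarray) -> FrameField:
    """Parallel-transport a normal frame along the tangent field.

    For t >= 1 the previous frame's columns are orthogonally projected off
    the current tangent, B(t) = (I − uuᵀ) A(t−1) with u the unit tangent,
    and re-orthonormalized by replacing the singular values of B(t) with
    ones (nearest matrix with orthonormal columns).

    Raises
    ------
    DegenerateGeometryError
        On a zero tangent, or when B(t) becomes rank-deficient (the
        tangent flipped by ~180° in one step).
    """
    tangents = np.asarray(tangents, dtype=float)
    if tangents.ndim != 2 or tangents.shape[1] != 3:
        raise ValidationError("tangents must be (n, 3)")
    norms = np.linalg.norm(tangents, axis=1)
    bad = np.nonzero(norms < 1e-12)[0]
    if len(bad):
        raise DegenerateGeometryError("zero tangent vector", index=int(bad[0]))

    n = len(tangents)
    frames = np.empty((n, 3, 2))
    frames[0] = _initial_frame(tangents[0])
    for t in range(1, n):
        u = tangents[t] / norms[t]
        prev = frames[t - 1]
        b = prev - np.outer(u, u @ prev)
        uu, s, vt = np.linalg.svd(b, full_matrices=False)
        if s[-1] < 1e-8:
            raise DegenerateGeometryError(
                "rank-deficient projected frame; tangent jumped ~90°", index=t
            )
        frames[t] = uu @ vt
    return FrameField(frames=frames)


def flatten(trace, backbone: BackboneCurve, frames: FrameField) -> FlatCurve:
    """φ(t) = A(t)ᵀ (γ(t) − γ_σ(t)): the chain seen in the moving frame."""
    coords = np.asarray(getattr(trace, "coords", trace), dtype=float)
    if not (len(coords) == len(backbone) == len(frames)):
        raise ValidationError(
            "trace, backbone and frames must have identical length"
        )
    offset = coords - backbone.points
    pts = np.einsum("tik,ti->tk", frames.frames, offset)
    return FlatCurve(points=pts)
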