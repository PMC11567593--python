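"""Repeat-unit delineation and scoring of external motif predictions.

A correctly delineated solenoid winds exactly once around its core
between consecutive repeat starts.  Given motif start residues R_1 < … <
R_ℓ predicted by an external tool (e.g. an LxxLxL motif classifier), the
discrepancy

    D(R_1, …, R_ℓ) = Σ_{j=2..ℓ} (W(R_j) − W(R_{j−1}) − 1)²

measures how far the predictions depart from one-winding-per-repeat.
Duplicate predictions a few residues apart contribute a term close to
(0 − 1)² = 1 each and are flagged.  The best-fit integer grid offset — the
c ∈ [0, 1) minimizing the squared distance of W(R_j) − c to the integers —
aligns the winding's integer crossings with the predicted starts for
side-by-side comparison, and drives repeat delineation from the winding
profile itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .segmentation import SegmentAnnotation
from .winding import WindingProfile, integer_crossings

FLAG_THRESHOLD = 0.5


@dataclass(frozen=True)
class MotifSet:
    """Ordered motif-start residue indices (internal t coordinates)."""

    starts: np.ndarray
    source: str = ""

    def __post_init__(self):
        starts = np.asarray(self.starts, dtype=int)
        object.__setattr__(self, "starts", starts)
        if len(starts) >= 2 and not np.all(np.diff(starts) > 0):
            raise ValidationError("motif starts must be strictly increasing")

    def __len__(self) -> int:
        return len(self.starts)


@dataclass(frozen=True)
class DiscrepancyResult:
    value: float
    per_interval: np.ndarray  # W(R_j) − W(R_{j−1}) − 1, length ℓ−1
    grid_offset: float
    flagged_pairs: tuple[tuple[int, int], ...]  # (j−1, j) motif index pairs


@dataclass(frozen=True)
class RepeatDelineation:
    unit_starts: np.ndarray
    unit_lengths: np.ndarray


def discrepancy(
    profile: WindingProfile | np.ndarray,
    motifs: MotifSet,
    flag_threshold: float = FLAG_THRESHOLD,
) -> DiscrepancyResult:
    """Discrepancy of motif starts against the winding profile.

    ``flagged_pairs`` lists consecutive motif index pairs whose interval
    winding differs from 1 by more than ``flag_threshold`` revolutions
    (duplicates wind ≈ 0 between them and are caught this way).
    """
    values = profile.values if isinstance(profile, WindingProfile) else np.asarray(profile)
    starts = motifs.starts
    if len(starts) < 2:
        raise ValidationError("need at least 2 motif starts for a discrepancy")
    bad = (starts < 0) | (starts >= len(values))
    if np.any(bad):
        raise ValidationError(
            f"motif start t={int(starts[np.nonzero(bad)[0][0]])} outside profile"
        )
    w = values[starts]
    per_interval = np.diff(w) - 1.0
    value = float(np.sum(per_interval**2))
    flagged = tuple(
        (int(j), int(j + 1))
        for j in np.nonzero(np.abs(per_interval) > flag_threshold)[0]
    )
    offset = best_integer_grid(values, motifs)
    return DiscrepancyResult(
        value=value,
        per_interval=per_interval,
        grid_offset=offset,
        flagged_pairs=flagged,
    )


def _grid_objective(w: np.ndarray, c: np.ndarray | float) -> np.ndarray | float:
    d = w - np.atleast_1d(np.asarray(c, dtype=float))[:, None]
    frac = d - np.round(d)
    obj = np.sum(frac**2, axis=1)
    return obj if np.ndim(c) else float(obj[0])


def best_integer_grid(
    profile: WindingProfile | np.ndarray,
    motifs: MotifSet,
    coarse_step: float = 1e-3,
) -> float:
    """Offset c ∈ [0, 1) of the integer grid nearest W at the motif starts.

    Minimizes Σ_j dist(W(R_j) − c, ℤ)² by a coarse scan at ``coarse_step``
    refined with bounded 1-D minimization around the best grid point.
    """
    values = profile.values if isinstance(profile, WindingProfile) else np.asarray(profile)
    starts = motifs.starts
    if len(starts) < 2:
        raise ValidationError("need at least 2 motif starts")
    w = values[starts]
    grid = np.arange(0.0, 1.0, coarse_step)
    obj = _grid_objective(w, grid)
    c0 = float(grid[int(np.argmin(obj))])

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(
        lambda c: _grid_objective(w, float(c)),
        bounds=(c0 - coarse_step, c0 + coarse_step),
        method="bounded",
        options={"xatol": 1e-9},
    )
    best = float(res.x) % 1.0
    # the coarse minimum itself may beat the refined edge in pathological ties
    if _grid_objective(w, best) > obj.min():
        best = c0
    return best


def delineate_repeats(
    profile: WindingProfile | np.ndarray,
    annotation: SegmentAnnotation,
    offset: float = 0.0,
) -> RepeatDelineation:
    """Repeat-unit starts: integer crossings of W within the coil spans."""
    starts_all = []
    lengths_all = []
    for span in annotation.lrr_spans:
        crossings = integer_crossings(profile, span, offset)
        starts_all.extend(int(c) for c in crossings)
        if len(crossings) >= 2:
            lengths_all.extend(int(d) for d in np.diff(crossings))
    return RepeatDelineation(
        unit_starts=np.array(starts_all, dtype=int),
        unit_lengths=np.array(lengths_all, dtype=int),
    )
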