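"""Synthetic α-carbon traces of solenoid proteins with known ground truth.

The generator emulates the geometry the annotation pipeline targets: an
optional non-coiling N-terminal segment, a helical solenoid of
configurable period (residues per turn), tube radius and axial rise,
optional straight "hairpin" excursions inserted mid-coil, and a
non-coiling C-terminal tail.  Within the coil, residue i sits at phase
α_i = 2π·i/period on a circle of the given radius in the plane normal to
the (optionally gently curved) core axis, so the analytic winding rate is
exactly 1/period and every stage of the pipeline can be tested against
construction-time truth without downloading structures.

The default period (25) and radius match the repeat geometry of
leucine-rich repeat domains (repeat units of ~20-30 residues).  Flanking
segments are self-avoiding correlated random walks with 3.8 Å steps (an
α-helix option exists); the coil itself follows the analytic
parametrization, which is an idealization rather than a stereochemically
valid backbone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .structure_io import CalphaTrace

CA_STEP = 3.8  # Å, Cα-Cα distance used for flanks and excursions


@dataclass(frozen=True)
class SolenoidSpec:
    """Parameters of a synthetic solenoid trace.

    insertions: list of (start_turn, length) straight non-coiling
    excursions; start_turn is measured in turns from the coil start.
    """

    n_pre: int = 0
    period: float = 25.0
    n_turns: float = 8.0
    radius: float = 14.0
    rise: float = 1.5
    axis_curvature: float | None = None  # radius of curvature of the core, Å
    insertions: tuple[tuple[float, int], ...] = ()
    n_post: int = 0
    noise_sd: float = 0.0
    seed: int = 0
    flank: str = "walk"  # "walk" | "helix"

    def __post_init__(self):
        if self.period <= 4:
            raise ValidationError("period must exceed 4 residues/turn")
        if self.n_pre < 0 or self.n_post < 0 or self.n_turns <= 0:
            raise ValidationError("lengths must be non-negative, n_turns positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.flank not in ("walk", "helix"):
            raise ValidationError("flank must be 'walk' or 'helix'")
        for ins in self.insertions:
            if len(ins) != 2 or ins[1] < 0:
                raise ValidationError("insertions must be (start_turn, length>=0)")


def _axis_frame(spec: SolenoidSpec, s: np.ndarray):
    """Core-axis points and parallel normal frames at arc lengths s."""
    if spec.axis_curvature is None:
        axis = np.column_stack([np.zeros_like(s), np.zeros_like(s), s])
        nrm = np.tile([1.0, 0.0, 0.0], (len(s), 1))
        binrm = np.tile([0.0, 1.0, 0.0], (len(s), 1))
        return axis, nrm, binrm
    rho = float(spec.axis_curvature)
    ang = s / rho
    axis = np.column_stack(
        [rho * (1.0 - np.cos(ang)), np.zeros_like(s), rho * np.sin(ang)]
    )
    # planar arc: Frenet normal stays in-plane, binormal constant; for a
    # planar curve this coincides with parallel transport (zero torsion)
    nrm = np.column_stack([np.cos(ang), np.zeros_like(s), -np.sin(ang)])
    binrm = np.tile([0.0, 1.0, 0.0], (len(s), 1))
    return axis, nrm, binrm


def _random_walk(rng, start, first_dir, n, existing, step=CA_STEP, min_sep=3.0):
    """Correlated self-avoiding random walk of n points leaving ``start``.

    Direction persistence (~3-residue decorrelation) mimics chain
    stiffness; candidate steps clashing with recently placed points are
    re-drawn with progressively stronger steering.
    """
    pts = []
    pos = np.asarray(start, dtype=float)
    d = np.asarray(first_dir, dtype=float)
    d /= np.linalg.norm(d)
    occupied = list(existing)
    for _ in range(n):
        trial_dir = d
        for attempt in range(30):
            cand = pos + step * trial_dir
            near = False
            for q in occupied[-200:]:
                if np.linalg.norm(cand - q) < min_sep:
                    near = True
                    break
            if not near:
                break
            # steer away progressively harder
            trial_dir = d + (0.5 + 0.2 * attempt) * rng.standard_normal(3)
            trial_dir /= np.linalg.norm(trial_dir)
        pos = pos + step * trial_dir
        pts.append(pos.copy())
        occupied.append(pos.copy())
        # persistence: new direction correlates with the old
        d = trial_dir + 0.35 * rng.standard_normal(3)
        d /= np.linalg.norm(d)
    return np.array(pts)


def _helix_flank(start, direction, n, rng):
    """Ideal α-helix flank: 1.5 Å rise/residue, 2.3 Å radius, 3.6 res/turn."""
    direction = np.asarray(direction, dtype=float)
    direction /= np.linalg.norm(direction)
    # orthonormal completion
    e = np.zeros(3)
    e[int(np.argmin(np.abs(direction)))] = 1.0
    u = e - (e @ direction) * direction
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)
    i = np.arange(1, n + 1, dtype=float)
    ang = 2.0 * np.pi * i / 3.6
    pts = (
        np.asarray(start)
        + np.outer(1.5 * i, direction)
        + 2.3 * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
    )
    return pts


def generate(spec: SolenoidSpec) -> tuple[CalphaTrace, dict]:
    """Generate a trace and its ground truth, deterministically per seed.

    Ground truth keys: ``lrr_span`` (half-open index interval of the coil
    including insertions), ``repeat_starts`` (indices where the analytic
    phase crosses multiples of 2π), ``insertions`` (index intervals),
    ``phase`` (per-residue analytic phase, NaN off-coil), ``period``,
    ``n_turns``, ``analytic_winding`` (total turns of the coil).
    """
    rng = np.random.default_rng(spec.seed)
    n_coil = int(round(spec.period * spec.n_turns))
    if n_coil < 2:
        raise ValidationError("coil must contain at least 2 residues")

    inserts = sorted(
        ((int(round(st * spec.period)), int(length)) for st, length in spec.insertions),
        key=lambda p: p[0],
    )
    for pos, _ in inserts:
        if not (0 < pos < n_coil):
            raise ValidationError("insertion start_turn must fall inside the coil")

    alpha = 2.0 * np.pi * np.arange(n_coil) / spec.period
    s = spec.rise * np.arange(n_coil, dtype=float)
    axis, nrm, binrm = _axis_frame(spec, s)
    coil = axis + spec.radius * (
        nrm * np.cos(alpha)[:, None] + binrm * np.sin(alpha)[:, None]
    )

    # splice insertions: straight out-and-back excursions at 3.8 Å steps
    pieces = []  # (coords, kind, phase values or nan)
    prev = 0
    for pos, length in inserts:
        pieces.append((coil[prev:pos], "coil", alpha[prev:pos]))
        if length > 0:
            anchor = coil[pos - 1] if pos > 0 else coil[0]
            outward = nrm[pos] * np.cos(alpha[pos]) + binrm[pos] * np.sin(alpha[pos])
            lateral = binrm[pos] * np.cos(alpha[pos]) - nrm[pos] * np.sin(alpha[pos])
            half = length // 2
            out_pts = [anchor + CA_STEP * (i + 1) * outward for i in range(half)]
            back_pts = [
                anchor
                + 1.9 * lateral
                + CA_STEP * (length - half - i) * outward
                for i in range(length - half)
            ]
            exc = np.array(out_pts + back_pts)
            pieces.append((exc, "insertion", np.full(length, np.nan)))
        prev = pos
    pieces.append((coil[prev:], "coil", alpha[prev:]))

    mid_coords = np.concatenate([p[0] for p in pieces])
    mid_phase = np.concatenate([p[2] for p in pieces])
    kinds = np.concatenate([[p[1]] * len(p[0]) for p in pieces])

    # flanks
    if spec.n_pre > 0:
        if spec.flank == "walk":
            first_dir = -(mid_coords[1] - mid_coords[0])
            pre = _random_walk(
                rng, mid_coords[0], first_dir, spec.n_pre, [mid_coords[0]]
            )[::-1]
        else:
            first_dir = -(mid_coords[1] - mid_coords[0])
            pre = _helix_flank(mid_coords[0], first_dir, spec.n_pre, rng)[::-1]
    else:
        pre = np.empty((0, 3))
    if spec.n_post > 0:
        last_dir = mid_coords[-1] - mid_coords[-2]
        if spec.flank == "walk":
            post = _random_walk(
                rng, mid_coords[-1], last_dir, spec.n_post, [mid_coords[-1]]
            )
        else:
            post = _helix_flank(mid_coords[-1], last_dir, spec.n_post, rng)
    else:
        post = np.empty((0, 3))

    coords = np.concatenate([pre, mid_coords, post])
    n_total = len(coords)
    if spec.noise_sd > 0:
        coords = coords + rng.normal(0.0, spec.noise_sd, coords.shape)

    # ground truth in final index space
    span_start = len(pre)
    span_end = len(pre) + len(mid_coords)
    phase = np.concatenate(
        [np.full(len(pre), np.nan), mid_phase, np.full(len(post), np.nan)]
    )
    ins_intervals = []
    offset = span_start
    cursor = 0
    for coords_piece, kind, _ in pieces:
        if kind == "insertion":
            ins_intervals.append((offset + cursor, offset + cursor + len(coords_piece)))
        cursor += len(coords_piece)

    # repeat starts: coil indices whose analytic phase first reaches 2πk
    repeat_starts = []
    k = 0
    for idx in range(n_total):
        if np.isnan(phase[idx]):
            continue
        if phase[idx] >= 2.0 * np.pi * k - 1e-12:
            repeat_starts.append(idx)
            k += 1

    plddt = np.where(
        (np.arange(n_total) >= span_start) & (np.arange(n_total) < span_end),
        90.0,
        60.0,
    )
    for a, b in ins_intervals:
        plddt[a:b] = 70.0

    trace = CalphaTrace(
        chain_id="A",
        residue_ids=np.arange(1, n_total + 1),
        coords=coords,
        plddt=plddt,
        sequence="A" * n_total,
    )
    ground_truth = {
        "lrr_span": (span_start, span_end),
        "repeat_starts": np.array(repeat_starts, dtype=int),
        "insertions": tuple(ins_intervals),
        "phase": phase,
        "period": spec.period,
        "n_turns": spec.n_turns,
        "analytic_winding": n_coil / spec.period,
    }
    return trace, ground_truth


_AA3 = {"A": "ALA", "G": "GLY", "L": "LEU", "X": "UNK"}


def write_trace(trace: CalphaTrace, path: str | Path) -> None:
    """Write a minimal valid PDB with one CA ATOM record per residue.

    The B-factor column carries pLDDT (or 0 when absent); coordinates are
    written at PDB fixed-width precision (1e-3 Å), so a read/write round
    trip agrees to that precision.
    """
    path = Path(path)
    lines = []
    for i in range(len(trace)):
        aa = trace.sequence[i] if trace.sequence else "A"
        res3 = _AA3.get(aa, "ALA")
        b = float(trace.plddt[i]) if trace.plddt is not None else 0.0
        x, y, z = trace.coords[i]
        lines.append(
            f"ATOM  {i + 1:5d}  CA  {res3:>3} {trace.chain_id[:1] or 'A'}"
            f"{int(trace.residue_ids[i]):4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b:6.2f}          "
            f"{'C':>2}"
        )
    lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
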