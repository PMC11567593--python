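"""Read protein structures into α-carbon traces and write annotation output.

All downstream mathematics indexes residues by the dense 0-based curve
parameter ``t``; only this module translates between ``t`` and the author
residue numbering found in structure files.  AlphaFold-style models store
the per-residue confidence (pLDDT, 0-100) in the B-factor column, which is
surfaced verbatim as :attr:`CalphaTrace.plddt`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    ChainNotFoundError,
    DegenerateInputError,
    FormatError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Consecutive Cα atoms further apart than this (Å) trigger a chain-break
#: warning; the trace is still treated as a consecutive discrete curve.
CHAIN_BREAK_DISTANCE = 4.5


@dataclass(frozen=True)
class CalphaTrace:
    """An ordered α-carbon trace: the discrete space curve γ(t), t = 0..n.

    Parameters
    ----------
    chain_id : str
        Chain label from the source file.
    residue_ids : ndarray of int
        Author residue numbers, strictly increasing (1-based as in file).
        Numbering gaps are preserved; the internal parameter ``t`` stays
        dense.
    coords : (n, 3) ndarray of float
        Cα coordinates in Å.
    plddt : ndarray of float, optional
        Per-residue confidence in [0, 100] (B-factor column).
    sequence : str, optional
        One-letter amino-acid string of equal length.
    """

    chain_id: str
    residue_ids: np.ndarray
    coords: np.ndarray
    plddt: np.ndarray | None = None
    sequence: str | None = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        rids = np.asarray(self.residue_ids, dtype=int)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "residue_ids", rids)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValidationError("coords must be an (n, 3) array")
        n = len(coords)
        if n < 2:
            raise DegenerateInputError(f"trace needs >= 2 residues, got {n}")
        if len(rids) != n:
            raise ValidationError("residue_ids and coords length mismatch")
        if not np.all(np.diff(rids) > 0):
            raise ValidationError("residue_ids must be strictly increasing")
        if not np.all(np.isfinite(coords)):
            raise ValidationError("coords contain non-finite values")
        if self.plddt is not None:
            plddt = np.asarray(self.plddt, dtype=float)
            object.__setattr__(self, "plddt", plddt)
            if len(plddt) != n:
                raise ValidationError("plddt length mismatch")
        if self.sequence is not None and len(self.sequence) != n:
            raise ValidationError("sequence length mismatch")

    def __len__(self) -> int:
        return len(self.coords)

    def t_of_residue(self, residue_number: int) -> int:
        """Map an author residue number to the internal index ``t``."""
        hits = np.nonzero(self.residue_ids == residue_number)[0]
        if len(hits) == 0:
            raise ValidationError(
                f"residue {residue_number} not present in chain {self.chain_id}"
            )
        return int(hits[0])


def _one_letter(resname: str) -> str:
    try:
        import gemmi

        info = gemmi.find_tabulated_residue(resname)
        if info is not None:
            code = info.one_letter_code.upper()
            if code.isalpha():
                return code
    except Exception:  # pragma: no cover - tabulation is best-effort
        pass
    return "X"


def read_calpha_trace(path: str | Path, chain: str | None = None) -> CalphaTrace:
    """Read a PDB or mmCIF file into a :class:`CalphaTrace`.

    One entry per residue possessing an α-carbon, in residue-number order;
    the first altloc wins.  When more than one chain contains α-carbons the
    chain must be named explicitly; with a single candidate chain it is
    selected automatically.

    Raises
    ------
    FormatError
        If the file cannot be parsed.
    ChainNotFoundError
        If the requested chain is absent, or no chain is requested while
        several chains carry α-carbons.
    DegenerateInputError
        If fewer than two α-carbons are found.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        structure = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if len(structure) == 0:
        raise FormatError(f"{path} contains no models")
    model = structure[0]

    candidates = []
    for ch in model:
        if any(atom.name == "CA" for res in ch for atom in res):
            candidates.append(ch.name)
    if chain is None:
        if len(candidates) == 0:
            raise DegenerateInputError(f"{path}: no chain contains α-carbons")
        if len(candidates) > 1:
            raise ChainNotFoundError(
                f"{path}: multiple chains with α-carbons ({candidates}); "
                "specify one explicitly"
            )
        chain = candidates[0]
    elif chain not in [ch.name for ch in model]:
        raise ChainNotFoundError(f"chain {chain!r} not found in {path}")

    ch = model[chain]
    rows = []  # (resnum, xyz, b, one_letter)
    for res in ch:
        ca = None
        for atom in res:
            if atom.name == "CA":
                ca = atom  # first altloc encountered
                break
        if ca is None:
            continue
        rows.append(
            (
                res.seqid.num,
                (ca.pos.x, ca.pos.y, ca.pos.z),
                ca.b_iso,
                _one_letter(res.name),
            )
        )
    if len(rows) < 2:
        raise DegenerateInputError(
            f"{path} chain {chain}: fewer than 2 α-carbons ({len(rows)})"
        )
    rows.sort(key=lambda r: r[0])
    residue_ids = np.array([r[0] for r in rows], dtype=int)
    coords = np.array([r[1] for r in rows], dtype=float)
    plddt = np.array([r[2] for r in rows], dtype=float)
    sequence = "".join(r[3] for r in rows)

    gaps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    n_breaks = int(np.sum(gaps > CHAIN_BREAK_DISTANCE))
    if n_breaks:
        logger.warning(
            "%s chain %s: %d consecutive Cα pairs further than %.1f Å apart; "
            "treating the trace as a consecutive curve",
            path,
            chain,
            n_breaks,
            CHAIN_BREAK_DISTANCE,
        )
    return CalphaTrace(
        chain_id=chain,
        residue_ids=residue_ids,
        coords=coords,
        plddt=plddt,
        sequence=sequence,
    )


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def _segment_labels(n: int, annotation) -> list[str]:
    """Per-residue segment label from a SegmentAnnotation."""
    labels = ["flank"] * n
    bps = list(annotation.breakpoints)
    for i, (a, b) in enumerate(zip(bps[:-1], bps[1:])):
        if i % 2 == 1:
            lab = "coil"
        elif 0 < i < len(bps) - 2:
            lab = "non_coiling"  # interior constant segment (k=4 insertion)
        else:
            lab = "flank"
        for t in range(a, min(b, n)):
            labels[t] = lab
    return labels


def write_annotation(
    trace: CalphaTrace,
    annotation,
    repeats,
    path: str | Path,
    profile=None,
    phase=None,
    anomalies=None,
) -> None:
    """Write the per-residue TSV and the GFF3 feature file.

    ``path`` is a base path; ``<path>.tsv`` and ``<path>.gff3`` are
    produced.  GFF3 coordinates are 1-based inclusive in author residue
    numbers: a half-open span t ∈ [a, b) maps to
    ``residue_ids[a] .. residue_ids[b-1]``.

    Parameters
    ----------
    annotation : SegmentAnnotation
    repeats : RepeatDelineation or None
    profile : WindingProfile, optional
        Supplies the per-residue winding column.
    phase : PhaseProfile, optional
        Supplies phase (and SWL2D via ``anomalies``) columns where defined.
    anomalies : AnomalyProfile, optional
    """
    import pandas as pd

    path = Path(path)
    n = len(trace)
    winding = np.full(n, np.nan)
    if profile is not None:
        winding[: len(profile.values)] = profile.values
    phase_col = np.full(n, np.nan)
    if phase is not None:
        for t, theta in zip(phase.residue_indices, phase.phase):
            if 0 <= t < n:
                phase_col[t] = theta
    swl2d_col = np.full(n, np.nan)
    if anomalies is not None and phase is not None:
        offset = anomalies.residue_offset
        for i, v in enumerate(anomalies.swl2d):
            t = offset + i
            if 0 <= t < n:
                swl2d_col[t] = v

    df = pd.DataFrame(
        {
            "t": np.arange(n),
            "residue_id": trace.residue_ids,
            "winding": winding,
            "segment": _segment_labels(n, annotation),
            "phase": phase_col,
            "swl2d": swl2d_col,
        }
    )
    df.to_csv(path.with_suffix(".tsv"), sep="\t", index=False, float_format="%.6f")

    seqid = trace.chain_id or "chain"
    lines = ["##gff-version 3"]

    def feature(ftype: str, a: int, b: int, attrs: str, score: str = ".") -> str:
        # [a, b) in t-space -> 1-based inclusive residue numbers
        start = int(trace.residue_ids[a])
        end = int(trace.residue_ids[min(b, n) - 1])
        return "\t".join(
            [seqid, "lrrwind", ftype, str(start), str(end), score, ".", ".", attrs]
        )

    for i, (a, b) in enumerate(annotation.lrr_spans):
        lines.append(feature("solenoid_domain", a, b, f"ID=lrr_span_{i}"))
    bps = list(annotation.breakpoints)
    for i in range(2, len(bps) - 2, 2):
        lines.append(
            feature("non_coiling_region", bps[i], bps[i + 1], f"ID=insertion_{i//2}")
        )
    if repeats is not None:
        starts = list(repeats.unit_starts)
        lengths = list(repeats.unit_lengths)
        for i, s in enumerate(starts):
            e = s + (lengths[i] if i < len(lengths) else 1)
            e = min(e, n)
            if e <= s:
                continue
            lines.append(feature("repeat_unit", s, e, f"ID=repeat_{i}"))
    if anomalies is not None:
        for i, (a, b) in enumerate(anomalies.anomalies):
            a_t = anomalies.residue_offset + a
            b_t = anomalies.residue_offset + b
            a_t = max(0, min(a_t, n - 1))
            b_t = max(a_t + 1, min(b_t, n))
            lines.append(
                feature("non_coiling_region", a_t, b_t, f"ID=swl2d_anomaly_{i}")
            )
    path.with_suffix(".gff3").write_text("\n".join(lines) + "\n")


def read_motif_starts(path: str | Path, trace: CalphaTrace) -> np.ndarray:
    """Read motif-start residue numbers (LRRPredictor-style) into t indices.

    Accepts either one residue number per line, or a TSV with a
    ``residue_number`` column (optionally alongside ``protein_id``).
    Residue numbers are 1-based author numbers and are mapped through
    ``trace.residue_ids``; an unmapped residue is an error.
    """
    path = Path(path)
    numbers: list[int] = []
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValidationError(f"{path}: no motif starts found")
    header = lines[0].split("\t")
    if any(not _is_int(tok) for tok in header):
        try:
            col = header.index("residue_number")
        except ValueError:
            col = len(header) - 1
        body = lines[1:]
    else:
        col = len(header) - 1
        body = lines
    for ln in body:
        tok = ln.split("\t")[col]
        if not _is_int(tok):
            raise ValidationError(f"{path}: non-integer residue number {tok!r}")
        numbers.append(int(tok))
    ts = np.array(sorted(trace.t_of_residue(r) for r in numbers), dtype=int)
    return ts


def _is_int(tok: str) -> bool:
    try:
        int(tok)
        return True
    except ValueError:
        return False
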