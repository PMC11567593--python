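"""End-to-end annotation: geometry → winding → segmentation → repeats → phase.

:func:`annotate_structure` runs the full method on a
:class:`~lrrwind.structure_io.CalphaTrace` and returns every intermediate
product, so the CLI, the tests and downstream analysis all share one code
path.  The winding profile is oriented positive (the initial frame's
handedness is arbitrary; the recorded ``handedness`` flag preserves the
raw chirality), segmentation identifies the coiling span(s), integer
crossings of the winding delineate repeat units, and — when the span is
long enough — Laplacian circular coordinates provide per-residue phase
and the SWL2D anomaly profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .errors import LrrwindError
from .geometry import FlatCurve, flatten, parallel_transport_frames, smooth_backbone
from .laplacian_phase import AnomalyProfile, PhaseProfile, phase_from_trace, swl2d
from .repeat_validation import (
    DiscrepancyResult,
    MotifSet,
    RepeatDelineation,
    delineate_repeats,
    discrepancy,
)
from .segmentation import SegmentAnnotation, SegmentationConfig, annotate_domain
from .structure_io import CalphaTrace
from .winding import WindingProfile, cumulative_winding

logger = logging.getLogger(__name__)


@dataclass
class AnnotationResult:
    trace: CalphaTrace
    winding: WindingProfile
    handedness: int
    annotation: SegmentAnnotation
    repeats: RepeatDelineation
    grid_offset: float = 0.0
    phase: PhaseProfile | None = None
    anomalies: AnomalyProfile | None = None
    motif_discrepancy: DiscrepancyResult | None = None
    warnings: tuple[str, ...] = ()

    def summary(self) -> dict:
        ann = self.annotation
        slope = ann.slope
        out = {
            "slope": slope,
            "period": (1.0 / slope) if slope else None,
            "breakpoints": list(ann.breakpoints),
            "k": ann.k,
            "lrr_rms": ann.lrr_rms,
            "lrr_spans": [list(s) for s in ann.lrr_spans],
            "handedness": self.handedness,
            "n_repeats": int(len(self.repeats.unit_starts)),
            "repeat_starts": self.repeats.unit_starts.tolist(),
            "unit_lengths": self.repeats.unit_lengths.tolist(),
            "grid_offset": self.grid_offset,
            "n_warnings": len(self.warnings),
            "warnings": list(self.warnings),
        }
        if self.motif_discrepancy is not None:
            out["discrepancy"] = self.motif_discrepancy.value
            out["flagged_pairs"] = [list(p) for p in self.motif_discrepancy.flagged_pairs]
        if self.anomalies is not None:
            out["anomaly_intervals"] = [
                [int(a + self.anomalies.residue_offset), int(b + self.anomalies.residue_offset)]
                for a, b in self.anomalies.anomalies
            ]
        return out


def annotate_structure(
    trace: CalphaTrace,
    config: RunConfig | None = None,
    motifs: MotifSet | None = None,
    with_phase: bool = True,
) -> AnnotationResult:
    """Run the full annotation method on an α-carbon trace."""
    cfg = config or RunConfig()
    warnings: list[str] = []

    backbone = smooth_backbone(trace.coords, cfg.sigma, cfg.kernel_truncation_sigmas)
    frames = parallel_transport_frames(backbone.tangents)
    flat = flatten(trace, backbone, frames)
    raw = cumulative_winding(flat)
    profile = raw.oriented()
    handedness = profile.handedness

    seg_cfg = SegmentationConfig(
        d_min=cfg.d_min,
        d_max=cfg.d_max,
        c_weight=cfg.c_weight,
        d_weight=cfg.d_weight,
        rms_threshold=cfg.rms_threshold,
        epsilon=cfg.epsilon,
        max_iter=cfg.max_iter,
        seed=cfg.seed,
    )
    annotation = annotate_domain(profile, seg_cfg)
    if not annotation.converged:
        warnings.append("breakpoint descent did not fully converge")

    result_discrepancy = None
    offset = 0.0
    if motifs is not None and len(motifs) >= 2:
        result_discrepancy = discrepancy(profile, motifs, cfg.flag_threshold)
        offset = result_discrepancy.grid_offset
    repeats = delineate_repeats(profile, annotation, offset)

    phase = None
    anomalies = None
    if with_phase and annotation.lrr_spans:
        # domain envelope: from the first coil span to the last, so the
        # anomaly statistic sees any non-coiling insertion between them
        span = (annotation.lrr_spans[0][0], annotation.lrr_spans[-1][1])
        needed = cfg.window + cfg.knn + 2
        if span[1] - span[0] > needed:
            try:
                phase = phase_from_trace(
                    trace,
                    span,
                    window=cfg.window,
                    knn=cfg.knn,
                    sigma=cfg.phase_sigma,
                )
                anomalies = swl2d(
                    phase.laplacian_winding,
                    annotation.slope,
                    window=cfg.swl2d_window,
                    residue_offset=int(phase.residue_indices[0]),
                )
            except LrrwindError as exc:
                warnings.append(f"phase estimation failed: {exc}")
        else:
            warnings.append(
                f"coil span {span} too short for phase estimation (needs > {needed})"
            )

    return AnnotationResult(
        trace=trace,
        winding=profile,
        handedness=handedness,
        annotation=annotation,
        repeats=repeats,
        grid_offset=offset,
        phase=phase,
        anomalies=anomalies,
        motif_discrepancy=result_discrepancy,
        warnings=tuple(warnings),
    )
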