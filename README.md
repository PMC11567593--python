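# lrrwind

Structure-aware annotation of solenoid repeat domains — leucine-rich
repeats (LRRs) in particular — from the α-carbon trace of a protein
structure.

## The problem

LRR domains are curved solenoids built from tandem repeat units of
~20–30 residues.  Sequence-based annotators (profile HMMs, motif
classifiers) routinely mis-place domain boundaries and repeat starts,
because divergent repeats stop looking like the training motifs even
though the *coil geometry* is perfectly conserved.  With predicted
structures now available genome-wide, the geometry itself can do the
annotation: a solenoid is exactly a region where the chain winds around
a core curve at a constant rate.

`lrrwind` implements that idea as an unsupervised pipeline over the
discrete space curve γ(t) of Cα positions:

1. **Backbone.**  γ_σ = γ ⋆ g_σ, a Gaussian smoothing (σ = 20 residues)
   that averages the coil away and leaves its core curve.
2. **Framing.**  An orthonormal basis A(t) of the plane normal to
   γ′_σ(t) is parallel-transported along the backbone: project A(t−1)
   off the new tangent and re-orthonormalize via the orthogonal
   Procrustes solution (SVD with singular values set to 1).
3. **Flattening.**  φ(t) = A(t)ᵀ(γ(t) − γ_σ(t)) — the chain as seen by
   an observer riding the backbone.
4. **Winding.**  The cumulative winding number
   W(t) = W(t−1) + (1/2π)·atan2(⟨φ(t−1)×φ(t)⟩, ⟨φ(t−1),φ(t)⟩)
   counts signed revolutions about the origin.  In a solenoid W is
   linear with slope 1/period.
5. **Slope voting.**  Every secant of W with length in [100, 250] casts
   a score (b−a)/(1+R_ab) for its slope, where R_ab is the squared
   deviation of W from that secant; the winning bin gives the median
   slope m (a Hough-style vote).
6. **Segmentation.**  A discontinuous clipped-ReLU regression —
   constant / slope-m / constant, with loss
   L = Σ C·V(flat segments)(W) + D·V(sloped segments)(W − m·t),
   C = 1, D = 1.5 — is fitted by finite-difference gradient descent on
   the breakpoints.  If the coil-segment RMS exceeds 1.0 revolutions,
   the model is refitted with four breakpoints, carving a non-coiling
   insertion out of the coil.
7. **Repeats & validation.**  Integer crossings of W delineate repeat
   units.  External motif predictions R_1 < … < R_ℓ are scored by the
   discrepancy D = Σ_j (W(R_j) − W(R_{j−1}) − 1)², which is 0 exactly
   when the structure winds once between consecutive predictions —
   duplicate predictions stand out as ~(0−1)² terms.
8. **Phase & anomalies.**  Inside the domain, σ = 1 tangents are
   delay-embedded (window 24 → 75 dimensions), a 50-mutual-nearest-
   neighbor graph is built, and the two lowest delocalized nonzero
   modes of its unweighted Laplacian give circular coordinates
   θ(t) = atan2(y, x).  The sliding-window L² distance (SWL2D) between
   the resulting winding and a slope-m line spikes at hairpins and
   other non-coiling anomalies.

A synthetic-solenoid generator with exact ground truth (period, domain
boundaries, insertions, per-residue phase) makes every stage testable
without downloading structures.

## Worked example

Simulate an NLR-like protein — 150 flanking residues, a 20-turn LRR coil
of period 25, 150 more flanking residues, 0.3 Å coordinate noise — and
annotate it:

```bash
$ lrrwind simulate -o nlr_like.pdb --n-pre 150 --n-turns 20 --n-post 150 \
      --noise-sd 0.3 --seed 42
wrote nlr_like.pdb (800 residues)

$ lrrwind annotate nlr_like.pdb -o out
{"period": 25.01514523253011, "k": 2, "lrr_rms": 0.04915717878242617,
 "lrr_spans": [[172, 649]], "n_repeats": 20}
```

Reading the output: the secant vote recovered the repeat period to
within 0.02 residues of the true 25; the two-breakpoint model (`k: 2`)
sufficed because the coil RMS 0.049 is far below the refit threshold
1.0 (no insertion); the coil spans residues 172–649 (truth: 150–650 —
the smoothing blurs the elbows of W by a few residues, see
`docs/methods.md`); and 20 integer crossings of W delineate the repeat
units.  `out/nlr_like.tsv` holds the per-residue winding/segment/phase
profile, `out/nlr_like.gff3` the domain and repeat features
(1-based inclusive residue coordinates):

```
##gff-version 3
A	lrrwind	solenoid_domain	173	649	.	.	.	ID=lrr_span_0
A	lrrwind	repeat_unit	194	219	.	.	.	ID=repeat_0
```

With an LRRPredictor-style motif file (`--motifs starts.tsv`, one
residue number per line or a `residue_number` column), `annotate` and
`discrepancy` additionally emit the discrepancy score and flag motif
pairs winding far from one revolution apart — the signature of
duplicated or missing predictions.  `batch` runs a directory of
structures into a corpus table; `phase` reports the Laplacian phase
wrap count.

Library use mirrors the CLI:

```python
import lrrwind as lw

trace = lw.read_calpha_trace("nlr_like.pdb")
result = lw.annotate_structure(trace)
result.annotation.lrr_spans    # ((172, 649),)
result.repeats.unit_lengths    # array([26, 24, 26, ...])
```

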