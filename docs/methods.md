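# Methods

This note records the model, the numerical choices, and the limits of
what the test suite demonstrates.  It assumes the pipeline overview in
the README.

## Model and assumptions

The package treats a protein chain as a discrete space curve
γ(t) ∈ ℝ³, t = 0..n, and a solenoid domain as a region where γ winds at
a constant rate around a smooth core curve.  Everything downstream is a
consequence of that single geometric assumption:

* the Gaussian-smoothed curve γ_σ approximates the core (the coil
  averages out when σ is large compared to the period: a sinusoid of
  period p survives smoothing with amplitude exp(−(2πσ/p)²/2), which is
  ~3·10⁻⁶ for p = 25, σ = 20);
* the flattened curve φ(t) = A(t)ᵀ(γ − γ_σ) then orbits the origin, so
  the cumulative winding number W is linear in the coil with slope
  1/period and roughly flat elsewhere;
* boundary detection reduces to changepoint regression on W.

The method is unsupervised: no training data, no sequence information.
It presumes a *linear* solenoid (the core curve does not close on
itself) and at most one non-coiling insertion per domain (models with
two and four breakpoints only).

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| σ (backbone) | 20 | residues | smoothing width; must sit well above the period and below the domain length |
| kernel truncation | ±4σ | residues | support of the discrete kernels |
| d_min, d_max | 100, 250 | residues | secant lengths admitted to the slope vote |
| C, D | 1, 1.5 | — | loss weights for flat / sloped segments |
| RMS threshold | 1.0 | revolutions | coil-RMS above which the 4-breakpoint model is used |
| ε | 2 | residues per unit gradient | descent step, halved on failure (backtracking) |
| max_iter | 2000 | — | descent iteration cap |
| window | 24 | residues | delay-embedding window (≈ one repeat; embedding dimension 3·25 = 75) |
| k (graph) | 50 | — | mutual-nearest-neighbor count |
| σ (phase tangents) | 1 | residues | small width that preserves per-repeat loop structure |
| SWL2D threshold | median + 3·MAD | — | robust anomaly cutoff |
| duplicate flag | 0.5 | revolutions | \|ΔW − 1\| above which a motif pair is flagged |

The defaults are the method's published operating point; each is
exposed through `RunConfig` / CLI flags.

## Numerical choices

**Convolution boundaries.**  The infinite-support Gaussian is truncated
at ±4σ.  The smoothing kernel is renormalized to unit sum at every
output position, so constants are preserved exactly and termini are not
dragged toward zero (which would fabricate curvature).  The derivative
kernel is corrected to exact zero sum and scaled to map the unit ramp
to 1; the curve is extended by odd reflection before convolving, which
keeps linear curves exact at the ends.

**Initial frame.**  Any orthonormal completion of the initial tangent
is valid; for reproducibility the package uses a deterministic one
(Gram–Schmidt of the least-aligned standard basis vector, then a cross
product).  The handedness of this choice fixes the sign of W, which is
physically arbitrary; profiles are therefore oriented positive and the
raw chirality recorded as a `handedness` flag.

**Parallel transport.**  B(t) = (I − uuᵀ)A(t−1) followed by the
orthogonal-Procrustes projection (SVD, singular values → 1).  A
rank-deficient B(t) (tangent turning ~90° in one step) raises rather
than producing an arbitrary frame.

**Winding.**  The two-argument arctangent of the cross and dot products
of consecutive φ vectors gives the signed step angle in (−π, π] in all
quadrants.  Points within 10⁻⁹ Å of the origin raise — the angle is
meaningless there.  Integer crossings are reported at the first index
at or past the straddle; on a noisy profile a boundary can be crossed
more than once, which occasionally splits one repeat boundary into two
crossings a residue apart.

**Loss evaluation.**  Segment variances V are computed from globally
centered prefix sums, O(1) per segment; the test suite cross-checks
this against literal summation to 10⁻¹⁰.  Segments shorter than 2
contribute zero (the mean of an empty segment is undefined).

**Breakpoint descent.**  Interior breakpoints stay real-valued; the
loss is evaluated at rounded, order-repaired indices.  The gradient is
a forward difference of +1 residue.  Each iteration backtracks (step
halving) until the loss strictly decreases; convergence is declared
after 20 consecutive iterations with movement < 0.5.  Because the loss
is piecewise-constant in the real-valued breakpoints, sub-residue
gradient steps stall near an optimum; a greedy integer polish
(±8, ±3, ±1 single-coordinate moves) then settles the fit onto the
local integer optimum.  On the test corpora the polished descent
reproduces the exhaustive-search optimum.  Initialization is
slope-aware: the 10th/90th percentiles of positions whose local
25-residue secant slope exceeds m/2.  For k = 4 the extra pair brackets
the interior arg-min of the windowed local slope — a non-coiling
insertion is precisely a local flat in W — and a second, evenly-spaced
start is also descended, keeping the better loss; the k = 4 landscape
is multimodal and deviation-based initializations were observed to
select the wrong basin.

**Slope vote binning.**  The number of bins equals the number of
secants, capped at 5000 once it exceeds 10× the profile length; with
~10⁵ secants, one bin per secant adds nothing but memory.  The returned
slope is the left edge of the winning bin.

**Laplacian mode selection.**  The combinatorial Laplacian D − A of the
largest connected component (required to cover ≥ 90 % of the embedded
points) has one zero mode per component; the constant vector is always
excluded.  A structural anomaly hangs a pendant path off the otherwise
circular graph, and the path's string-like modes can have eigenvalues
far below the circle pair while being localized on a handful of
vertices.  Modes with participation ratio 1/(m·Σv⁴) below 0.35 are
therefore skipped (a sine mode scores 2/3; a mode localized on an
anomaly scores near zero), and the first two delocalized nonzero modes
become the circular coordinates.  On clean data this reduces exactly to
"the two smallest nonzero eigenvalues".  Eigenvector signs are
normalized (first appreciable entry positive) and the pair is reflected
so its winding trends positive, consistent with the main profile.

**Anomaly span.**  Phase and SWL2D are computed over the domain
envelope — from the first coil span to the last — so that an insertion
carved out by the 4-breakpoint model is still inside the analyzed
window.

## The synthetic generator

`synthetic_solenoid` produces Cα traces with exact ground truth: an
analytic helix (phase 2πt/period around a straight or gently curved
axis) flanked by correlated self-avoiding random walks, with optional
straight out-and-back "hairpin" excursions spliced into the coil.

Geometry: period 25, tube radius 14 Å, rise 1.5 Å/residue.  These are
mutually consistent with protein stereochemistry — the Cα–Cα step along
the coil is √(rise² + (2r sin(π/p))²) ≈ 3.82 Å, inside the physical
3.6–4.0 Å range — and match real LRR proportions (a 25-residue repeat
at 3.8 Å per residue closes a loop of radius ≈ 95/2π ≈ 15 Å).  Flanks
use 3.8 Å steps with ~3-residue direction persistence.  The coil itself
is an idealized parametrization: no backbone dihedrals, no side chains,
no sequence realism.  Smaller radii can be requested (several geometry
tests use radius 3 to check analytic attenuation and flattening), but
then the trace is not stereochemically plausible.

What the generator does *not* emulate — and hence what passing tests do
not establish about real structures: irregular per-repeat geometry
(real repeats vary in length and radius), folded flanking domains with
secondary structure (the random-walk flanks wobble more than a packed
NB-ARC domain would in some respects and less in others), missing
residues, and AlphaFold-specific error modes (low-pLDDT disorder).
The pLDDT column it writes (90 coil / 70 insertion / 60 flank) is a
labeling convenience, not a confidence model.

## Measured behavior and known limitations

Problem sizes used throughout the tests and the acceptance script:
800-residue traces (150 + 500 + 150), 10–20 structures per corpus.
These sizes exercise every code path at full fidelity; a single
annotation takes well under a second.

* **Period** is recovered essentially exactly (±0.02 residues of 25)
  whenever the coil spans several secant lengths.
* **Boundaries** are intrinsically blurred: smoothing mixes ~σ residues
  of flank into the backbone near each elbow, and the flanks' own
  winding wobble (±0.5–1 revolution over 150 residues) shifts the
  loss-optimal breakpoint.  Median endpoint error is ~5–8 residues;
  individual seeds can be off by 20–30.  The fitted breakpoints match
  the exhaustive-search optimum of the loss — the residual error is a
  property of the objective under these conditions, not of the
  optimizer.
* **Insertion refinement** is threshold-limited: a 40-residue insertion
  at period 25 pauses W by 1.6 revolutions, whose step-function RMS
  over a mid-domain span is 1.6·√(f(1−f)) ≈ 0.79 < 1.0.  Crossing the
  threshold therefore depends on the extra winding loss from the
  smoothing bulge around the excursion, which is seed-dependent: about
  half of such structures trigger the 4-breakpoint refit.  When it
  triggers, the middle flat segment localizes the insertion
  essentially always.  Longer insertions (≥ 50 residues ≈ 2 periods)
  cross the threshold from the pause alone.
* **SWL2D** localizes small hairpins to within ~1 window; very large
  excursions can still degrade the Laplacian coordinates on some seeds
  (the pendant path outgrows the participation-ratio filter's
  assumptions), in which case the 4-breakpoint regression — not the
  spectral route — is the detector that works.
* **Phase wraps** count repeats minus the window overhead: a w-window
  embedding of an L-residue coil yields (L − w)/period wraps, one less
  than the turn count at the default sizes.
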