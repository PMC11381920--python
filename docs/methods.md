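# Methods

## The measurement problem

In a blastoderm-stage *Drosophila* embryo imaged end-on, BMP signaling is
read out as nuclear accumulation of a GFP-tagged co-Smad (Med-GFP) in live
embryos, or phospho-Mad immunostaining in fixed ones, and target-gene
transcription as sub-nuclear MS2/MCP dots. All quantities of interest are
functions of position along the dorsoventral (DV) circumference, so the
package's coordinate system is the arc-length fraction *x* from the dorsal
midline along the embryo outline, signed by side (*x* ∈ [−1, 1], folded to
[0, 1] only where left and right halves are combined).

## Geometry: annulus and unrolling

The outline is detected on the Gaussian-smoothed nuclear channel (filter
radius 5 px). Because the histogram is trimodal (background, cytoplasm,
bright nuclei), a plain two-class Otsu cut often isolates only the nuclear
ring; we therefore take the lowest threshold of a three-class Otsu and
re-center it midway between the background and foreground means, which
tracks the half-height of the embryo edge for both bimodal and trimodal
images.

The traced contour is resampled by arc length and low-pass filtered
circularly with a Gaussian of 15 px of arc. The filter is symmetric, so the
boundary is not phase-shifted; its scale is set by the failure mode it must
prevent: nuclei lying just under the surface scallop the detected outline
at the nucleus spacing (~30 px), and an inward offset of 122 px (18.36 µm
at 0.15 µm/px) folds over wherever the local radius of curvature falls
below the offset depth. At 15 px the scallops are attenuated to harmless
amplitude while a radius-R outline shrinks by only σ²/2R (≈ 0.3 px for an
embryo-scale outline). Offsets that still reverse direction along more than
1% of the contour are rejected as degenerate.

The annulus (outer contour to its 18.36 µm inward offset — a liberal
estimate of the apical–basal nucleus height, configurable) is unrolled by
bilinear sampling along the normal-depth/arc grid. Masks travel back by
scattering strip pixels to their rounded image positions and filling the
rounding pinholes from the nearest written pixel (nearest-neighbor, no
label mixing). A nucleus's DV coordinate is the arc column of its nearest
forward-map sample — robust to the lateral shear of deep columns, which on
an elliptical outline are not radial.

## Segmentation

Regional maxima of the lightly smoothed strip (σ = 2 px) seed a
marker-based watershed; spurious cytoplasmic maxima are kept deliberately,
because extra compartments only tighten the fit around true nuclei. A
per-column band outline (first/last rows where the smoothed column profile
crosses midway between its own 10th and 90th percentiles — a scale-free
rise/fall criterion; columns with no crossing inherit neighbors' values by
circular interpolation) discards compartments whose marker lies outside the
nuclear band. Each remaining compartment is binarized with its own Otsu
threshold; the union mask is cleaned by opening (disk radius 2 px) and
components below 400 px (strictly) or above 10× the frame's median
component area are dropped. The 400 px floor is a pixel-scale constant
(≈ 16 µm² at ~0.2 µm/px); reduced-scale synthetic profiles carry a
proportionally scaled floor.

Per-nucleus records hold centroid, DV coordinate, area, nuclear-channel
mean I_nuc, reporter mean and max I_max, and the off-spot mean I_mean
(reporter mean after removing the 5×5 neighborhood of the brightest pixel).
Components whose nuclear mean falls below half the frame's median are
rejected as cytoplasm that slipped through the band filter — without this,
their small I_nuc denominator produces spurious high dot scores.

## Gradient model and normalization

Nuclear reporter intensity versus DV position is fitted per frame to
I(x) = A·exp(−(x−µ)²/2σ²) + B by bounded nonlinear least squares
(trust-region reflective; A ≥ 0, σ ∈ (0.005, 1]). Initialization is
deterministic: µ₀ at the maximum of a 15-nucleus moving average, σ₀ = 0.15,
B₀ and A₀ from the 5th/95th intensity percentiles. µ is interpreted as the
gradient peak location (dorsal for the BMP readouts here). A frame whose
fit fails inherits the previous frame's parameters, logged.

Live intensities are divided by three multiplicative factors:
Calib_norm = (Calib_mean/1.74·10⁴)·(0.1/Calib_LP) per imaging session,
timecourse_norm = nuc_mean/(100·nuc_LP) per embryo, and curve_norm(x), a
unit-mean DV attenuation curve built per embryo from the nuclear channel
(30-nucleus sliding window per frame, linear interpolation onto 151 equally
spaced grid points, averaged over frames). The constants put each factor
near 1 at a typical session. The grid lives on the folded axis [0, 1]
(optical-path attenuation is assumed symmetric between halves, matching the
151-point contract). Because all three factors are scalars or per-nucleus
multipliers, their application order is irrelevant — a tested invariant.
Fixed embryos instead divide each reporter nucleus-wise by the nuclear
channel and then normalize affinely, (ratio − B)/A, with that channel's own
fit; a channel whose fitted amplitude is negligible is returned as
ratio − B so output stays finite.

## Multi-embryo averaging

Per-embryo fitted A, B, σ are smoothed over time (centered 10-frame moving
average, shrunken at edges) and averaged across embryos into Ā(t), B̄(t),
σ̄(t). Each embryo's DV coordinates are rescaled by χ_k(t) = σ̄(t)/σ_k(t)
(stretching or compressing the axis so all gradients share the ensemble
width); rescaled |x| > 1 is dropped — the gradient has decayed to basal
there. Intensities are normalized to (I − B_k)/A_k, pooled, de-normalized
with Ā, B̄, folded, and binned onto the 36-point mesh (dx = 1/35; bin 1
covers [0, dx/2), bin 36 covers [1 − dx/2, 1]). Empty bins are linearly
interpolated and flagged; per-bin s.e.m. is reported. Frames are aligned
across embryos by time before gastrulation, supplied per embryo in the run
configuration.

## Control embryos

Controls carry the nuclear marker but no reporter; their reporter channel
is DV-averaged per frame. The first microscope set shows a slow unexplained
oscillation of roughly 9 min period, removed with a centered boxcar whose
width equals one oscillation period: a boxcar of width L attenuates a
sinusoid of period T by |sinc(L/T)|, which is exactly zero at L = T (a
1.5-period window, by contrast, would leave ≈ 21% of the amplitude).
Each microscope set is then normalized by β_norm, the mean of its filtered
curves over embryos and time, making sets from different instruments
comparable.

## Spot calling and domain boundary

Each record (nucleus × z-slice × time point) scores
S = (I_max − I_mean)/I_nuc. Per time point, the threshold is the
θ = 0.98 quantile (linear interpolation between order statistics) of S
pooled over all z-slices; is_dot ⇔ S ≥ threshold. Pooling over the stack is
what makes a 2% tail sensible: a transcribing nucleus appears in ~n_z
records but its dot is sharp in essentially one slice, so with dot
probability p ≈ 0.8, domain fraction w ≈ 0.27 and n_z = 12 slices the
dot-positive fraction of records is p·w/n_z ≈ 1.8% — just inside the tail.
The generator reproduces exactly this regime, and reduced-scale profiles
keep n_z at full scale because the statistic depends on that fraction.

Per half of the embryo (folded coordinates), the boundary maximizes
score(x₀) = #{dots, x ≤ x₀} − γ·#{non-dots, x ≤ x₀} with γ = 1 − θ = 0.02;
candidates are the observed nucleus positions (the score is piecewise
constant between them), ties break dorsally. A half with no dots has an
empty domain (boundary 0, flagged). The frame's width is the mean of the
two halves, which cancels midline placement errors to first order — a
tested property (±3 nucleus spacings of midline shift move the width by
less than one spacing). The midline itself is a configuration input with an
automatic fallback (circular median of dot positions). Time courses are
summarized as mean ± s.d. of per-frame widths; ensembles as per-embryo
means ± s.e.m.

## The synthetic embryo generator

The generator renders what the pipeline measures, nothing more:

* Elliptical outline (semi-axes 70 × 60 µm) centered in a 1024×1024,
  16-bit frame at 0.15 µm/px; nuclei are flat-core disks with a Gaussian
  edge (radius 2.2 µm, edge width 15% of radius), placed at jittered equal
  arc spacing ~2.9 µm under the surface. The default 80 nuclei per
  cross-section approximate the ~100-nucleus circumference of cycle-14
  embryos while leaving segmentable gaps.
* Reporter values follow the Gaussian gradient at each nucleus's DV
  coordinate, times a per-nucleus multiplicative factor (default CV 5%);
  cytoplasm carries a configurable fraction of the local signal (0.5 for
  the reporter, 0.15 for the nuclear marker), emulating nuclear enrichment.
  A single 1-px Gaussian blur stands in for the PSF; additive Gaussian read
  noise (s.d. 40 counts against ~3000-count nuclei, ≈ 1.3% of dynamic
  range) is quantized to uint16. The default live trajectory refines from
  (A, σ) = (2, 0.35) to (10, 0.12) at B = 2 over the time course.
* MS2 stacks give every nucleus one record per z-slice; a domain nucleus
  (|x| ≤ 0.27) carries a dot with probability 0.8 per frame, planted as a
  ≤3×3 cluster at a fixed offset from the centroid in one randomly chosen
  slice, with peak amplitude 0.8× the local nuclear signal.
* Controls render a spatially uniform reporter background modulated by a
  sinusoid (default period 9 min, amplitude 10%).
* The fixed-embryo mode renders two reporter channels from one shared
  Gaussian field with independent per-nucleus noise of fraction f = 0.20
  per channel. This value is derived, not fitted: with DV positions uniform
  on [−1, 1] and the default field (A = 10, B = 2, σ = 0.15), the expected
  across-nuclei Pearson correlation between the channels is
  ρ = Var(s)/(Var(s) + f²·E[s²]) = 1/(1 + 2.54 f²), so f = 0.20 targets
  ρ ≈ 0.91 — the regime reported for pMad/Med-GFP co-staining.

What the generator does **not** emulate: chromatin texture, mitotic
domains, photobleaching, stage drift, z-dependent PSF broadening, or
nucleus tracking across frames (every frame is analyzed independently, as
the pipeline assumes). Passing tests therefore certify the measurement
chain — geometry, segmentation, normalization, statistics — not robustness
to those real-data complications.

## Numerical choices and degenerate inputs

* A *noiseless* generator profile (hard-edged nuclei, no blur, no noise,
  equal cytoplasmic fractions in both channels) defines the idealized
  round-trip condition. Equal fractions matter: they make the per-nucleus
  signal/nuclear ratio exactly the generating gradient no matter how
  tightly the mask hugs the nucleus, so the full imaging round trip is
  required to recover (A, B, µ, σ) to 0.1%. With unequal fractions
  (the realistic default) mask-edge dilution rescales A and B by a common
  ~1% factor, which the affine normalization removes.
* Strip row 0 samples the outer boundary and row H−1 the inner boundary
  (endpoints inclusive), so a full-strip mask maps back onto the whole
  annulus.
* The arc origin (dorsal midline of the synthetic frames) is the vertex of
  a parabola fitted to the near-topmost run of the outline — the raw argmin
  wanders along the flat top of a wide ellipse.
* Constant strips: regional maxima degenerate to a single whole-plateau
  marker; the band outline flags the strip as degenerate and keeps
  everything; compartments with < 16 px or zero variance contribute empty
  masks, logged.
* Quantile convention: linear interpolation between order statistics,
  threshold comparison ≥. All identical scores make the call degenerate
  (all positive, flagged).
* Dot calling with fewer than 50 records warns — the 98th percentile of a
  small sample is unstable.

## Benchmark problem sizes

The two ensemble benchmarks (also run by `scripts/acceptance.py`) use eight
embryos each, seeds `base_seed + k`. The correlation ensemble runs at the
full 1024² scale. The MS2 ensemble runs at 512²/0.30 µm px with 70 nuclei,
5 time points and the full 12-slice stacks (component floor scaled to
100 px); the z-count is kept at full scale because the dot-record fraction,
which the percentile threshold lives on, depends on it. These sizes
reproduce the statistical regime of the full-scale configuration with an
ensemble that a laptop analyzes in about two minutes.

## Known limitations

* The boundary estimate sits at the most ventral dot-bearing nucleus, so it
  is biased dorsally by about half a nucleus spacing at dot probability
  0.8; the recovered ensemble width (~25% DV for a planted 27%) reflects
  this, well inside the biological spread it is compared against.
* Percentile pooling is over the whole z-stack; per-slice pooling would
  change thresholds for strongly z-dependent backgrounds.
* The DV attenuation curve is folded (symmetric between halves); a
  genuinely one-sided optical artifact would not be corrected.
* Embryo outlines more concave than the smoothed-contour assumption (e.g.
  deep furrows at late gastrulation) can degenerate the annulus; the
  pipeline rejects rather than guesses.
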