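# embryograd

Quantitative image analysis of BMP signaling gradients and target-gene
transcription in cross-sections of blastoderm-stage *Drosophila* embryos,
built for live two-channel confocal time-lapse data (a nuclear marker such
as histone-RFP plus a signaling or transcription reporter such as nuclear
Med-GFP or MS2/MCP-GFP) and for fixed co-stained embryos (pMad + Med-GFP).

The embryo, imaged end-on, is a roughly elliptical disk whose ~100 cortical
nuclei form a thin annular layer under the surface. The pipeline:

1. **Unrolls** the nuclear-layer annulus (default depth 18.36 µm inside the
   detected outline) into a rectangular strip parameterized by arc-length
   fraction and normal depth, and assigns every nucleus a dorsoventral (DV)
   coordinate *x* ∈ [−1, 1] — arc fraction from the dorsal midline, ±1 at
   the ventral midline.
2. **Segments nuclei** in the strip: regional maxima seed a marker-based
   watershed whose compartments are thresholded one-by-one with Otsu's
   method (robust to brightness variation between nuclei), cleaned by
   morphological opening and a strict 400-pixel component floor, and mapped
   back to image coordinates.
3. **Fits the gradient** of per-nucleus reporter intensity versus DV
   position with the Gaussian model

   *I*(*x*) = *A* exp(−(*x* − *µ*)² / 2*σ*²) + *B*

   (amplitude *A*, basal level *B*, peak *µ*, width *σ*), after a
   three-layer multiplicative normalization: a per-session laser
   calibration factor Calib_norm = (Calib_mean/1.74·10⁴)·(0.1/Calib_LP), a
   per-embryo brightness factor timecourse_norm = nuc_mean/(100·nuc_LP), and
   a 151-point DV attenuation curve built from the nuclear channel.
4. **Averages embryos** by rescaling each embryo's DV axis with
   χ_k(t) = σ̄(t)/σ_k(t) so all gradients share the ensemble width, pooling
   affinely normalized intensities, and binning onto a 36-point DV mesh
   (spacing d*x* = 1/35 ≈ 0.0286, half-width edge bins).
5. **Calls nascent-transcript dots** in MS2 z-stacks with the score
   *S* = (*I*_max − *I*_mean)/*I*_nuc per nucleus per slice (5×5
   neighborhood of the brightest pixel removed for *I*_mean) and a
   per-time-point 98th-percentile threshold, then estimates the
   **expression-domain boundary** on each half of the embryo as the argmax
   of score(*x*₀) = #dots dorsal of *x*₀ − 0.02·#non-dots dorsal of *x*₀,
   averaging the two halves so the exact midline position is immaterial.

A synthetic embryo generator (`embryograd.synth`) renders all of these
situations with complete ground truth — elliptical outline, annular nuclei,
refining DV gradient, nuclear/cytoplasmic contrast, planted sub-nuclear
dots in a 27%-DV dorsal domain, and oscillating no-reporter controls — so
the entire pipeline is testable end to end without microscope data.

## Worked example

Recover the transcription-domain width from one synthetic MS2 z-stack time
course:

```python
from embryograd import synth, pipeline

cfg = synth.SyntheticConfig.ms2_default(n_frames=5, rng_seed=1)
series, truth = synth.generate_ms2_stack(cfg)          # 5 frames x 12 z
result = pipeline.ms2_domain_analysis(series, min_size=cfg.min_component_px)
print(f"true half-width {truth.true_domain_halfwidth:.2f} DV")
print(f"recovered width {result.summary['mean_width']:.3f} "
      f"+/- {result.summary['sd_width']:.3f} s.d. over "
      f"{result.summary['n_frames']} frames")
```

prints

```
true half-width 0.27 DV
recovered width 0.257 +/- 0.000 s.d. over 5 frames
```

i.e. the 98th-percentile dot calls plus the penalized boundary statistic
recover the planted 27%-DV domain to within about one nucleus spacing: the
estimate sits at the most ventral dot-bearing nucleus, slightly inside the
true edge — and for this embryo the per-frame argmax lands on the same edge
nuclei in every frame, so the per-frame widths do not scatter at all.

The numbered drivers under `analysis/` run the full studies — fixed-embryo
two-channel correlation, live-gradient fitting, five-embryo averaging, the
eight-embryo MS2 width ensemble, and control-background normalization —
each printing what it found and writing tables under `results/`.

The `embryograd` CLI exposes the same runs from a shell
(`embryograd synth|fixed-correlation|live-gradient|average|ms2-domain`,
each taking a YAML config, output directory and seed).

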