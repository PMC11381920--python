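"""Ensemble recovery benchmarks run by the acceptance machinery and tests.

Both benchmarks generate a fixed-size synthetic ensemble at the module's
canonical study conditions, run the *full* pipeline (boundary detection,
unrolling, watershed segmentation, intensity extraction, normalization,
scoring) and measure how well the known generating quantity is recovered.
"""

from __future__ import annotations

from . import pipeline, synth


def domain_width_benchmark(
    n_embryos: int = 8, base_seed: int = 1, n_frames: int = 5
) -> dict:
    """Recovered expression-domain width over an MS2 z-stack ensemble.

    Generates ``n_embryos`` MS2 time courses at the default dot-domain
    configuration (true half-width 0.27 DV, dot probability 0.8, default
    noise; embryo k uses seed base_seed + k), runs spot scoring, per-time-
    point 98th-percentile calling, penalized boundary argmax with gamma =
    0.02 and left/right averaging, and returns the ensemble summary of the
    per-embryo time-course mean widths (plus the generating truth).
    """
    per_embryo = []
    cfg0 = synth.SyntheticConfig.ms2_default(n_frames=n_frames)
    for k in range(n_embryos):
        cfg = cfg0.model_copy(update={"rng_seed": base_seed + k})
        series, _ = synth.generate_ms2_stack(cfg)
        result = pipeline.ms2_domain_analysis(
            series, min_size=cfg.min_component_px or 400
        )
        per_embryo.append(result.summary)
    from .spots import ensemble_width_summary

    summary = ensemble_width_summary(per_embryo)
    summary["true_halfwidth"] = cfg0.dot_domain_halfwidth
    summary["n_frames"] = n_frames
    return summary


def correlation_benchmark(n_embryos: int = 8, base_seed: int = 1) -> dict:
    """Recovered two-readout nuclear correlation over fixed-embryo sections.

    Generates ``n_embryos`` shared-field two-channel cross-sections at the
    default fixed-embryo configuration (embryo k uses seed base_seed + k),
    segments them, normalizes both channels (nuclear ratio then Gaussian
    affine normalization) and returns the per-embryo Pearson correlations
    with their ensemble mean and s.d.
    """
    cfg0 = synth.SyntheticConfig.fixed_default()
    embryos = []
    for k in range(n_embryos):
        cfg = cfg0.model_copy(update={"rng_seed": base_seed + k})
        nuc, ch1, ch2, _ = synth.generate_fixed_embryo(cfg)
        embryos.append((nuc, ch1, ch2))
    _, rhos, mean, sd = pipeline.fixed_correlation_analysis(
        embryos, cfg0.pixel_size, min_size=cfg0.min_component_px or 400
    )
    return {
        "per_embryo_rho": rhos,
        "mean_rho": mean,
        "sd_rho": sd,
        "n_embryos": len(rhos),
    }
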