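"""End-to-end analyses tying geometry, segmentation, gradient and spots.

Each public function runs one of the study's analyses on an in-memory image
or series and returns tidy tables; file I/O, configuration and the CLI live
in :mod:`embryograd.run` / :mod:`embryograd.cli`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geometry, segmentation, spots
from .errors import FitError
from .gradient import (
    GradientFit,
    NormalizationContext,
    correlate_channels,
    dv_norm_curve,
    fit_gaussian,
)
from .series import EmbryoImageSeries

log = logging.getLogger(__name__)


def analyze_cross_section(
    nuclear: np.ndarray,
    signal: np.ndarray,
    pixel_size: float,
    layer_depth: float = geometry.DEFAULT_LAYER_DEPTH_UM,
    min_size: int = segmentation.MIN_COMPONENT_PX,
    max_size: int | None = None,
    midline: float = 0.0,
    frame: int = 0,
    z: int = 0,
    extra_channels: dict[str, np.ndarray] | None = None,
    transform: geometry.AnnulusTransform | None = None,
) -> tuple[pd.DataFrame, geometry.AnnulusTransform]:
    """Unroll, segment and extract nucleus records from one cross-section.

    If ``transform`` is given (e.g. reused across z-slices of one time
    point), boundary detection is skipped.  Returns (records, transform).
    """
    if transform is None:
        outer = geometry.detect_embryo_boundary(nuclear)
        transform = geometry.annulus_transform(outer, layer_depth, pixel_size)
    strip = geometry.unroll(nuclear, transform)
    labels = segmentation.segment_strip(strip, min_size=min_size, max_size=max_size)
    img_labels = geometry.map_mask_back(labels, transform, np.shape(nuclear))
    records = segmentation.extract_nuclei(
        img_labels,
        nuclear,
        signal,
        transform,
        midline=midline,
        frame=frame,
        z=z,
        extra_channels=extra_channels,
    )
    return records, transform


@dataclass
class LiveGradientResult:
    """Per-frame records, normalization context and Gaussian fits."""

    records: pd.DataFrame  # one row per nucleus per frame, with `intensity`
    fits: pd.DataFrame  # frame, A, B, mu, sigma, residual_norm, n_nuclei
    context: NormalizationContext
    fallback_frames: list[int] = field(default_factory=list)


def live_gradient_analysis(
    series: EmbryoImageSeries,
    context: NormalizationContext | None = None,
    layer_depth: float = geometry.DEFAULT_LAYER_DEPTH_UM,
    min_size: int = segmentation.MIN_COMPONENT_PX,
    midline: float = 0.0,
) -> LiveGradientResult:
    """Gradient time course of one live embryo.

    Segments every frame, builds the DV normalization curve from the nuclear
    channel, normalizes signal intensities (session x time course x DV
    curve), and fits the Gaussian model per frame.  A frame whose fit fails
    falls back to the previous frame's parameters (logged and recorded in
    ``fallback_frames``).
    """
    all_records = []
    for t in range(series.n_frames):
        rec, _ = analyze_cross_section(
            series.frame(t, 0),
            series.frame(t, 1),
            series.pixel_size,
            layer_depth=layer_depth,
            min_size=min_size,
            midline=midline,
            frame=t,
        )
        all_records.append(rec)
    records = pd.concat(all_records, ignore_index=True)
    if context is None:
        context = NormalizationContext()
    grid, curve = dv_norm_curve(records)
    context.x_grid, context.curve_norm = grid, curve
    records["intensity"] = context.normalize(
        records["mean_signal"].to_numpy(), records["dv"].to_numpy()
    )
    fits_rows = []
    fallback: list[int] = []
    prev: GradientFit | None = None
    for t, group in records.groupby("frame"):
        try:
            fit = fit_gaussian(group["dv"].to_numpy(), group["intensity"].to_numpy())
        except FitError as exc:
            if prev is None:
                raise
            log.warning("frame %s: %s; falling back to previous frame", t, exc)
            fallback.append(int(t))
            fit = prev
        prev = fit
        fits_rows.append({"frame": int(t), **fit.as_dict()})
    return LiveGradientResult(
        records=records,
        fits=pd.DataFrame(fits_rows),
        context=context,
        fallback_frames=fallback,
    )


def fixed_correlation_analysis(
    embryos: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    pixel_size: float,
    layer_depth: float = geometry.DEFAULT_LAYER_DEPTH_UM,
    min_size: int = segmentation.MIN_COMPONENT_PX,
) -> tuple[pd.DataFrame, list[float], float, float]:
    """Two-readout nuclear correlation across a set of fixed embryos.

    ``embryos`` holds (nuclear, signal1, signal2) image triples.  Each embryo
    is segmented, both signal channels are normalized (nuclear ratio plus
    Gaussian affine normalization) and correlated across nuclei.  Returns
    (pooled records, per-embryo rho, ensemble mean, ensemble s.d.).
    """
    per_embryo = []
    for k, (nuc, ch1, ch2) in enumerate(embryos):
        rec, _ = analyze_cross_section(
            nuc,
            ch1,
            pixel_size,
            layer_depth=layer_depth,
            min_size=min_size,
            extra_channels={"signal2": ch2},
        )
        rec["embryo"] = k
        per_embryo.append(rec)
    rhos, mean, sd = correlate_channels(per_embryo)
    return pd.concat(per_embryo, ignore_index=True), rhos, mean, sd


@dataclass
class Ms2DomainResult:
    """Scored and thresholded records plus per-frame domain boundaries."""

    calls: pd.DataFrame  # records with S, is_dot, threshold_value
    boundaries: pd.DataFrame  # frame, left/right boundary, width
    summary: dict  # mean_width, sd_width, n_frames
    midline_offset: float = 0.0


def ms2_domain_analysis(
    series: EmbryoImageSeries,
    theta: float = spots.THETA,
    gamma: float | None = None,
    layer_depth: float = geometry.DEFAULT_LAYER_DEPTH_UM,
    min_size: int = segmentation.MIN_COMPONENT_PX,
    midline: float = 0.0,
    refine_midline: bool = False,
) -> Ms2DomainResult:
    """Dot calling and domain-width time course for an MS2 z-stack series.

    The embryo outline of each time point is detected once (on the middle
    z-slice) and reused across slices; every slice is segmented and scored
    independently, the percentile threshold pools all slices of a time
    point, and the penalized boundary statistic uses every record.
    """
    if gamma is None:
        gamma = 1.0 - theta
    called = []
    for t in range(series.n_frames):
        mid_z = series.n_z // 2
        _, transform = analyze_cross_section(
            series.frame(t, 0, mid_z),
            series.frame(t, 1, mid_z),
            series.pixel_size,
            layer_depth=layer_depth,
            min_size=min_size,
            midline=midline,
            frame=t,
            z=mid_z,
        )
        frame_records = []
        for z in range(series.n_z):
            rec, _ = analyze_cross_section(
                series.frame(t, 0, z),
                series.frame(t, 1, z),
                series.pixel_size,
                layer_depth=layer_depth,
                min_size=min_size,
                midline=midline,
                frame=t,
                z=z,
                transform=transform,
            )
            frame_records.append(rec)
        scored = spots.score_records(pd.concat(frame_records, ignore_index=True))
        called.append(spots.call_dots(scored, theta))
    calls = pd.concat(called, ignore_index=True)
    offset = spots.estimate_midline_offset(calls) if refine_midline else 0.0
    boundaries = spots.find_boundaries(calls, gamma, midline_offset=offset)
    return Ms2DomainResult(
        calls=calls,
        boundaries=boundaries,
        summary=spots.width_time_course(boundaries),
        midline_offset=offset,
    )


def control_background_analysis(
    series_set: list[EmbryoImageSeries],
    oscillation_period: float | None = None,
    layer_depth: float = geometry.DEFAULT_LAYER_DEPTH_UM,
    min_size: int = segmentation.MIN_COMPONENT_PX,
) -> dict:
    """DV-averaged, low-pass-filtered, set-normalized control backgrounds.

    Returns a dict with per-embryo raw and filtered curves, the set's
    beta_norm and the normalized curves.
    """
    from .gradient import control_background, dv_averaged_intensity

    raw_curves = []
    for series in series_set:
        recs = []
        for t in range(series.n_frames):
            rec, _ = analyze_cross_section(
                series.frame(t, 0),
                series.frame(t, 1),
                series.pixel_size,
                layer_depth=layer_depth,
                min_size=min_size,
                frame=t,
            )
            recs.append(rec)
        curve = dv_averaged_intensity(pd.concat(recs, ignore_index=True))
        raw_curves.append(curve.sort_index().to_numpy())
    period_frames = (
        oscillation_period / series_set[0].time_resolution
        if oscillation_period
        else None
    )
    filtered, beta, normalized = control_background(raw_curves, period_frames)
    return {
        "raw": raw_curves,
        "filtered": filtered,
        "beta_norm": beta,
        "normalized": normalized,
    }


def align_frames(
    fits_or_records: pd.DataFrame,
    gastrulation_frame: int,
) -> pd.DataFrame:
    """Re-index frames as time-before-gastrulation (frame - gastrulation).

    Aligned frame 0 is gastrulation onset; earlier frames are negative, so
    identically staged events in different embryos share an index.
    """
    out = fits_or_records.copy()
    out["frame"] = out["frame"] - gastrulation_frame
    return out
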