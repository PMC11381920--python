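"""Nucleus segmentation in the unrolled strip.

The strategy follows the watershed-compartment idea: regional maxima of the
lightly smoothed strip seed a marker-based watershed whose ridge lines carve
the strip into one compartment per maximum (spurious cytoplasmic maxima are
deliberately kept — they only tighten the fit around true nuclei).  A
per-column band outline finds the rows occupied by the nuclear layer so that
cytoplasm-only compartments can be discarded, each remaining compartment is
thresholded with its own Otsu cut (a global threshold fails when nuclei vary
in brightness), and the union mask is cleaned by morphological opening plus
small/large-component removal (components below 400 px are artifacts at the
standard pixel scale).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation as sk_seg

from . import geometry
from .errors import OutsideAnnulusError

log = logging.getLogger(__name__)

MIN_COMPONENT_PX = 400


def find_markers(strip: np.ndarray, smooth_sigma: float = 2.0) -> np.ndarray:
    """Labeled regional maxima of the lightly smoothed strip.

    Every regional maximum becomes a marker, including spurious cytoplasmic
    ones.  A constant strip is a single plateau: it yields one marker covering
    the whole strip (scikit-image reports the plateau as one maximal region).
    """
    smoothed = ndimage.gaussian_filter(np.asarray(strip, dtype=float), smooth_sigma)
    maxima = morphology.local_maxima(smoothed, connectivity=2, allow_borders=True)
    markers, n = ndimage.label(maxima)
    if n == 0:
        # perfectly flat strip: treat the whole plateau as one marker
        markers = np.ones_like(markers)
    return markers


def watershed_compartments(strip: np.ndarray, markers: np.ndarray,
                           smooth_sigma: float = 2.0) -> np.ndarray:
    """Exhaustive partition of the strip into one compartment per marker."""
    if markers.max() < 1:
        raise ValueError("watershed requires at least one marker")
    smoothed = ndimage.gaussian_filter(np.asarray(strip, dtype=float), smooth_sigma)
    return sk_seg.watershed(-smoothed, markers)


@dataclass
class BandOutline:
    """Per-column (top, bottom) row limits of the nuclear band."""

    top: np.ndarray
    bottom: np.ndarray
    degenerate: bool = False

    def contains(self, row: float, col: int, slack: float = 2.0) -> bool:
        c = int(np.clip(col, 0, len(self.top) - 1))
        return self.top[c] - slack <= row <= self.bottom[c] + slack


def nuclear_band_outline(
    strip: np.ndarray,
    column_smooth: float = 2.0,
    outline_smooth: int = 31,
    contrast_floor: float = 0.05,
) -> BandOutline:
    """Find the rows occupied by nuclei in every strip column.

    Each smoothed column profile is scanned for the first and last rows where
    it crosses midway between its own 10th and 90th intensity percentiles (a
    scale-free rise/fall criterion).  Columns with no usable crossing (dark
    gaps between nuclei) inherit their neighbors' band by interpolation, and
    the outline is smoothed circularly across columns.  A strip with no
    contrast anywhere yields the full-height band flagged ``degenerate``.
    """
    sm = ndimage.gaussian_filter(np.asarray(strip, dtype=float), column_smooth)
    h, w = sm.shape
    p10 = np.percentile(sm, 10, axis=0)
    p90 = np.percentile(sm, 90, axis=0)
    global_contrast = np.percentile(sm, 90) - np.percentile(sm, 10)
    if global_contrast <= 0:
        log.warning("degenerate band: strip has no intensity contrast")
        return BandOutline(np.zeros(w), np.full(w, h - 1.0), degenerate=True)
    mid = 0.5 * (p10 + p90)
    valid = (p90 - p10) > contrast_floor * global_contrast
    above = sm >= mid[None, :]
    any_above = above.any(axis=0)
    valid &= any_above
    top = np.where(valid, np.argmax(above, axis=0).astype(float), np.nan)
    bottom = np.where(
        valid, (h - 1 - np.argmax(above[::-1], axis=0)).astype(float), np.nan
    )
    if not np.any(valid):
        log.warning("degenerate band: no column crossed its rise/fall criterion")
        return BandOutline(np.zeros(w), np.full(w, h - 1.0), degenerate=True)
    cols = np.arange(w)
    for arr in (top, bottom):
        bad = np.isnan(arr)
        if bad.any():
            # circular interpolation across the strip seam
            good = ~bad
            arr[bad] = np.interp(
                cols[bad], cols[good], arr[good], period=w
            )
    top = ndimage.uniform_filter1d(top, outline_smooth, mode="wrap")
    bottom = ndimage.uniform_filter1d(bottom, outline_smooth, mode="wrap")
    return BandOutline(top, bottom)


def per_compartment_otsu(
    strip: np.ndarray,
    compartments: np.ndarray,
    markers: np.ndarray | None = None,
    band: BandOutline | None = None,
    min_pixels: int = 16,
) -> np.ndarray:
    """Union of per-compartment Otsu masks over nucleus-bearing compartments.

    Each compartment is thresholded on its own intensities.  If ``markers``
    and ``band`` are given, compartments whose marker centroid falls outside
    the nuclear band are discarded as cytoplasm-only.  Compartments with fewer
    than ``min_pixels`` pixels or zero variance contribute nothing (logged).
    """
    strip = np.asarray(strip, dtype=float)
    out = np.zeros(strip.shape, dtype=bool)
    keep: set[int] | None = None
    if markers is not None and band is not None and not band.degenerate:
        keep = set()
        for region in measure.regionprops(markers):
            r, c = region.centroid
            if band.contains(r, int(round(c))):
                keep.add(region.label)
    for region in measure.regionprops(compartments):
        if keep is not None and region.label not in keep:
            continue
        sl = region.slice
        comp = compartments[sl] == region.label
        vals = strip[sl][comp]
        if vals.size < min_pixels:
            log.debug("compartment %d skipped: %d px", region.label, vals.size)
            continue
        if vals.max() <= vals.min():
            log.debug("compartment %d skipped: zero variance", region.label)
            continue
        th = filters.threshold_otsu(vals)
        out[sl] |= comp & (strip[sl] > th)
    return out


def clean_mask(
    mask: np.ndarray,
    min_size: int = MIN_COMPONENT_PX,
    max_size: int | None = None,
    opening_radius: int = 2,
) -> np.ndarray:
    """Morphological opening plus small/large-component removal, relabeled.

    Components strictly below ``min_size`` pixels are removed (a 400 px
    component survives).  ``max_size`` defaults to 10x the median surviving
    component area of the frame.
    """
    opened = morphology.opening(mask, morphology.disk(opening_radius))
    labels, n = ndimage.label(opened)
    if n == 0:
        return labels
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    survive = areas >= min_size
    if max_size is None:
        kept = areas[survive & (areas > 0)]
        max_size = int(10 * np.median(kept)) if kept.size else np.iinfo(np.int64).max
    survive &= areas <= max_size
    relabel = np.zeros(n + 1, dtype=np.int32)
    relabel[np.flatnonzero(survive)] = np.arange(1, int(survive.sum()) + 1)
    return relabel[labels]


def segment_strip(
    strip: np.ndarray,
    min_size: int = MIN_COMPONENT_PX,
    max_size: int | None = None,
    smooth_sigma: float = 2.0,
) -> np.ndarray:
    """Full strip segmentation: markers -> watershed -> band -> Otsu -> clean."""
    markers = find_markers(strip, smooth_sigma)
    compartments = watershed_compartments(strip, markers, smooth_sigma)
    band = nuclear_band_outline(strip)
    mask = per_compartment_otsu(strip, compartments, markers=markers, band=band)
    return clean_mask(mask, min_size=min_size, max_size=max_size)


@dataclass
class NucleusRecord:
    """One segmented nucleus in one frame/slice.

    ``mean_nuclear`` is I_nuc, ``max_signal`` I_max and
    ``mean_signal_minus_spot`` I_mean (the signal mean after removing the 5x5
    neighborhood of the brightest signal pixel) of the spot score
    S = (I_max - I_mean) / I_nuc.
    """

    label: int
    frame: int
    z: int
    row: float
    col: float
    dv: float
    area: int
    mean_nuclear: float
    mean_signal: float
    max_signal: float
    mean_signal_minus_spot: float

    @classmethod
    def from_row(cls, row: pd.Series) -> "NucleusRecord":
        return cls(**{f: row[f] for f in cls.__dataclass_fields__})


RECORD_COLUMNS = list(NucleusRecord.__dataclass_fields__)


def extract_nuclei(
    labels_img: np.ndarray,
    nuclear_img: np.ndarray,
    signal_img: np.ndarray,
    transform: geometry.AnnulusTransform,
    midline: float = 0.0,
    frame: int = 0,
    z: int = 0,
    extra_channels: dict[str, np.ndarray] | None = None,
    nuclear_floor_frac: float | None = 0.5,
) -> pd.DataFrame:
    """Per-nucleus intensity records from an image-frame labeled mask.

    Returns one row per label with centroid, DV coordinate, area and the
    intensity statistics of :class:`NucleusRecord`; ``extra_channels`` adds
    ``mean_<name>`` columns.  Nuclei whose centroid falls outside the annulus
    are dropped (logged), as are components whose nuclear-channel mean falls
    below ``nuclear_floor_frac`` of the frame's median — those are cytoplasm
    compartments that slipped through the band filter, and their small I_nuc
    denominator would corrupt downstream dot scores.
    """
    nuclear_img = np.asarray(nuclear_img, dtype=float)
    signal_img = np.asarray(signal_img, dtype=float)
    rows = []
    for region in measure.regionprops(labels_img):
        sl = region.slice
        comp = labels_img[sl] == region.label
        sig = signal_img[sl]
        nuc = nuclear_img[sl]
        vals = sig[comp]
        flat_idx = int(np.argmax(vals))
        rr, cc = np.nonzero(comp)
        r0, c0 = rr[flat_idx], cc[flat_idx]
        off_spot = comp & ~(
            (np.abs(np.arange(comp.shape[0])[:, None] - r0) <= 2)
            & (np.abs(np.arange(comp.shape[1])[None, :] - c0) <= 2)
        )
        centroid = region.centroid
        try:
            dv = geometry.assign_dv_coordinate(centroid, transform, midline)
        except OutsideAnnulusError:
            log.debug("label %d centroid outside annulus, dropped", region.label)
            continue
        rec = {
            "label": int(region.label),
            "frame": frame,
            "z": z,
            "row": centroid[0],
            "col": centroid[1],
            "dv": dv,
            "area": int(region.area),
            "mean_nuclear": float(nuc[comp].mean()),
            "mean_signal": float(vals.mean()),
            "max_signal": float(vals.max()),
            "mean_signal_minus_spot": (
                float(sig[off_spot].mean()) if off_spot.any() else np.nan
            ),
        }
        if extra_channels:
            for name, img in extra_channels.items():
                rec[f"mean_{name}"] = float(np.asarray(img, dtype=float)[sl][comp].mean())
        rows.append(rec)
    columns = RECORD_COLUMNS + [
        f"mean_{n}" for n in (extra_channels or {})
    ]
    out = pd.DataFrame(rows, columns=columns)
    if nuclear_floor_frac is not None and len(out):
        floor = nuclear_floor_frac * out["mean_nuclear"].median()
        low = out["mean_nuclear"] < floor
        if low.any():
            log.info(
                "dropping %d cytoplasm-level components (nuclear mean < %.0f)",
                int(low.sum()),
                floor,
            )
            out = out.loc[~low].reset_index(drop=True)
    return out
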