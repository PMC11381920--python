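"""Embryo outline detection and annulus unrolling.

A blastoderm-stage embryo imaged end-on is a roughly elliptical cross-section
whose cortical nuclei form a thin annular layer just under the surface.  The
functions here detect the embryo outline, construct the nuclear-layer annulus
(default depth 18.36 um, a liberal estimate of the apical-basal nucleus
height), unroll the annulus into a rectangular strip parameterized by
(arc-length fraction, normal depth), and map segmentation masks and
coordinates between strip and image frames.

The dorsoventral (DV) coordinate of a nucleus is its arc-length fraction along
the outer boundary measured from the dorsal midline, signed by side: 0 at the
midline, +1/-1 at the arc-length antipode (the ventral midline).  The sign
convention is clockwise-positive with the arc origin at the top of the image,
i.e. the right half of the image is positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw, filters, measure

from .errors import (
    AnnulusDegenerateError,
    EmbryoNotFoundError,
    MultipleEmbryosError,
    OutsideAnnulusError,
)

DEFAULT_LAYER_DEPTH_UM = 18.36


def detect_embryo_boundary(
    image: np.ndarray,
    filter_radius: float = 5.0,
    min_area_frac: float = 0.05,
    ambiguity_ratio: float = 0.5,
) -> np.ndarray:
    """Detect the outer embryo contour in a nuclear-channel frame.

    The image is smoothed with a 2-D Gaussian filter of ``filter_radius``
    pixels, thresholded with Otsu's method, and the largest connected bright
    region is traced.  Returns a closed contour as an (N, 2) array of
    (row, col) coordinates ordered so that, at the topmost point, the column
    index increases (clockwise on screen; see module docstring).

    Raises
    ------
    EmbryoNotFoundError
        If no bright region covers at least ``min_area_frac`` of the image.
    MultipleEmbryosError
        If a second region within ``ambiguity_ratio`` of the largest exists.
    """
    smoothed = ndimage.gaussian_filter(np.asarray(image, dtype=float), filter_radius)
    if smoothed.max() <= smoothed.min():
        raise EmbryoNotFoundError("no embryo found: image is constant")
    # split background from embryo with the lowest threshold of a
    # three-class Otsu (the bright nuclear ring dominates the upper
    # histogram), then re-center the cut midway between the background and
    # foreground means so the contour tracks the half-height of the edge
    try:
        split = filters.threshold_multiotsu(smoothed, classes=3)[0]
    except ValueError:
        split = filters.threshold_otsu(smoothed)
    bg_mean = smoothed[smoothed <= split].mean()
    fg_mean = smoothed[smoothed > split].mean()
    bw = smoothed > 0.5 * (bg_mean + fg_mean)
    labels = measure.label(bw)
    if labels.max() == 0:
        raise EmbryoNotFoundError("no embryo found: nothing above threshold")
    areas = np.bincount(labels.ravel())[1:]
    order = np.argsort(areas)[::-1]
    floor = min_area_frac * bw.size
    if areas[order[0]] < floor:
        raise EmbryoNotFoundError(
            f"no embryo found: largest region {areas[order[0]]} px "
            f"< {floor:.0f} px floor"
        )
    if len(order) > 1 and areas[order[1]] >= ambiguity_ratio * areas[order[0]]:
        raise MultipleEmbryosError("multiple embryos: two comparable regions")
    region = ndimage.binary_fill_holes(labels == order[0] + 1)
    contours = measure.find_contours(region.astype(float), 0.5)
    contour = max(contours, key=len)
    return _orient_clockwise(contour)


def _orient_clockwise(contour: np.ndarray) -> np.ndarray:
    """Order a closed contour so the column increases at the topmost point."""
    pts = np.asarray(contour, dtype=float)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    top = int(np.argmin(pts[:, 0]))
    nxt = pts[(top + 1) % len(pts)]
    # walk a few points ahead to get a stable tangent on pixelated contours
    ahead = pts[(top + 5) % len(pts)]
    dcol = (nxt[1] - pts[top, 1]) + (ahead[1] - pts[top, 1])
    if dcol < 0:
        pts = pts[::-1]
    return pts


@dataclass
class AnnulusTransform:
    """Mapping between the nuclear-layer annulus and its unrolled strip.

    ``outer`` and ``inner`` are (W, 2) arrays of (row, col) points, equally
    spaced in arc length along the smoothed outer boundary, with index 0 at
    the arc origin (topmost point of the outline).  Strip pixel (r, c) maps to
    the image point interpolated linearly between ``outer[c]`` (row 0) and
    ``inner[c]`` (row H-1).
    """

    outer: np.ndarray
    inner: np.ndarray
    strip_size: tuple[int, int]
    arc_origin: int = 0
    _maps: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def width(self) -> int:
        return self.strip_size[1]

    @property
    def height(self) -> int:
        return self.strip_size[0]

    def forward_map(self) -> np.ndarray:
        """Image coordinates of every strip pixel, shape (H, W, 2).

        Row 0 samples the outer boundary and row H-1 the inner boundary
        (depth endpoints inclusive).
        """
        if "fwd" not in self._maps:
            h, w = self.strip_size
            frac = (np.arange(h) / max(h - 1, 1))[:, None, None]
            self._maps["fwd"] = self.outer[None] * (1.0 - frac) + self.inner[None] * frac
        return self._maps["fwd"]

    def arc_fraction(self, column: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(column) / self.strip_size[1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "outer": self.outer.tolist(),
                "inner": self.inner.tolist(),
                "strip_size": list(self.strip_size),
                "arc_origin": self.arc_origin,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "AnnulusTransform":
        d = json.loads(text)
        return cls(
            outer=np.asarray(d["outer"], dtype=float),
            inner=np.asarray(d["inner"], dtype=float),
            strip_size=tuple(d["strip_size"]),
            arc_origin=int(d["arc_origin"]),
        )


def _equal_arc_resample(pts: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline at n equal arc-length positions."""
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    targets = np.arange(n) * total / n
    return np.stack(
        [np.interp(targets, arc, closed[:, 0]), np.interp(targets, arc, closed[:, 1])],
        axis=1,
    )


def _resample_contour(
    contour: np.ndarray,
    n_points: int | None = None,
    smoothing: float = 15.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-arc-length resampling of a smoothed closed contour.

    The contour is resampled densely by arc length and low-pass filtered
    circularly with a Gaussian of ``smoothing`` pixels of arc.  The filter is
    symmetric (no phase shift of the boundary) and its scale is chosen to
    iron out both pixel stair-steps and the scalloping that surface nuclei
    imprint on the detected outline — scallops at the nucleus spacing would
    otherwise fold the deep inward offset.  A radius-R circle shrinks by only
    ~smoothing^2/2R (sub-pixel for embryo-scale outlines).  Returns (points
    (W, 2), inward unit normals (W, 2)), rolled so index 0 is the topmost
    point and the traversal has increasing column there.
    """
    pts = np.asarray(contour, dtype=float)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    dense = _equal_arc_resample(pts, 8192)
    perimeter = np.sum(
        np.linalg.norm(np.diff(dense, axis=0, append=dense[:1]), axis=1)
    )
    if smoothing > 0:
        sigma_samples = smoothing / (perimeter / 8192)
        dense = np.stack(
            [
                ndimage.gaussian_filter1d(dense[:, 0], sigma_samples, mode="wrap"),
                ndimage.gaussian_filter1d(dense[:, 1], sigma_samples, mode="wrap"),
            ],
            axis=1,
        )
    if n_points is None:
        n_points = int(round(perimeter))
    points = _equal_arc_resample(dense, n_points)
    tangent = np.gradient(np.vstack([points[-1:], points, points[:1]]), axis=0)[1:-1]
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    normal = np.stack([-tangent[:, 1], tangent[:, 0]], axis=1)
    centroid = points.mean(axis=0)
    inward = np.sign(np.einsum("ij,ij->i", centroid[None] - points, normal))
    # majority vote: the offset direction must be consistent along the contour
    if np.median(inward) < 0:
        normal = -normal
    # roll so index 0 is the topmost point, direction col-increasing there;
    # on a flat-topped outline argmin alone is unstable, so take the center
    # of the contiguous run of near-topmost points
    top = _flat_top_index(points[:, 0])
    points = np.roll(points, -top, axis=0)
    normal = np.roll(normal, -top, axis=0)
    if points[1, 1] < points[0, 1]:
        points = np.roll(points[::-1], 1, axis=0)
        normal = np.roll(normal[::-1], 1, axis=0)
    return points, normal


def _flat_top_index(rows: np.ndarray, slack: float = 2.0) -> int:
    """Subsample-stable index of the topmost point of a closed contour.

    Contour rows carry sub-pixel ripple, so the raw argmin wanders along a
    flat top.  A parabola fitted to the contiguous run of near-minimal rows
    puts the origin at the vertex instead (wrap-around handled).
    """
    n = len(rows)
    near = rows <= rows.min() + slack
    if near.all():
        return 0
    if near[0] and near[-1]:
        shift = int(np.argmin(near))  # rotate the run off the seam
        near = np.roll(near, -shift)
    else:
        shift = 0
    idx = np.flatnonzero(near)
    stop = idx[-1]
    gaps = np.flatnonzero(np.diff(idx) > 1)
    if gaps.size:
        stop = idx[gaps[0]]
    run = np.arange(idx[0], stop + 1)
    center = float(run.mean())
    if run.size >= 5:
        r = np.roll(rows, -shift)[run]
        a2, a1, _ = np.polyfit(run - center, r, 2)
        if a2 > 1e-12:
            center = float(np.clip(center - a1 / (2.0 * a2), run[0], run[-1]))
    return int(round(shift + center)) % n


def compute_inner_boundary(
    outer: np.ndarray,
    depth: float = DEFAULT_LAYER_DEPTH_UM,
    pixel_size: float = 1.0,
) -> np.ndarray:
    """Offset the outer contour inward by ``depth`` um (depth/pixel_size px).

    Raises AnnulusDegenerateError if the offset contour self-intersects
    (depth exceeding the local radius of curvature / inradius).
    """
    points, normal = _resample_contour(outer)
    depth_px = depth / pixel_size
    inner = points + depth_px * normal
    _check_offset(inner, points)
    return inner


def _check_offset(inner: np.ndarray, outer: np.ndarray) -> None:
    """Reject inward offsets that reverse direction (self-intersection).

    The offset is degenerate where the inner contour stops advancing in the
    outer contour's traversal direction (depth beyond the local radius of
    curvature folds the offset back on itself).
    """
    step = np.diff(inner, axis=0, append=inner[:1])
    outer_tang = np.diff(outer, axis=0, append=outer[:1])
    forward = np.einsum("ij,ij->i", step, outer_tang)
    # isolated sub-pixel micro-folds from residual contour ripple are
    # harmless; a real fold (depth beyond the radius of curvature) reverses
    # a long stretch of the offset
    if np.mean(forward <= 0) > 0.01:
        raise AnnulusDegenerateError(
            "annulus degenerate: inward offset self-intersects"
        )
    area = 0.5 * np.abs(
        np.dot(inner[:, 1], np.roll(inner[:, 0], -1))
        - np.dot(inner[:, 0], np.roll(inner[:, 1], -1))
    )
    if area < 1.0:
        raise AnnulusDegenerateError("annulus degenerate: inner contour collapsed")


def annulus_transform(
    outer: np.ndarray,
    depth: float = DEFAULT_LAYER_DEPTH_UM,
    pixel_size: float = 1.0,
    strip_width: int | None = None,
) -> AnnulusTransform:
    """Build the strip transform for an outer contour and layer depth (um)."""
    points, normal = _resample_contour(outer, n_points=strip_width)
    depth_px = depth / pixel_size
    inner = points + depth_px * normal
    _check_offset(inner, points)
    height = max(1, int(round(depth_px)))
    return AnnulusTransform(
        outer=points, inner=inner, strip_size=(height, len(points))
    )


def unroll(image: np.ndarray, transform: AnnulusTransform) -> np.ndarray:
    """Sample the annulus onto the rectangular strip (bilinear)."""
    fwd = transform.forward_map()
    return ndimage.map_coordinates(
        np.asarray(image, dtype=float),
        [fwd[..., 0], fwd[..., 1]],
        order=1,
        mode="nearest",
    )


def map_mask_back(
    strip_mask: np.ndarray,
    transform: AnnulusTransform,
    image_shape: tuple[int, int],
) -> np.ndarray:
    """Transform a labeled strip mask back into image coordinates.

    Strip pixels are scattered onto their (rounded) image positions; pixels of
    the annulus left unassigned by rounding are filled from their nearest
    assigned neighbor (nearest-neighbor assignment, no label mixing).
    """
    strip_mask = np.asarray(strip_mask)
    if strip_mask.shape != transform.strip_size:
        raise ValueError(
            f"mask shape {strip_mask.shape} != strip size {transform.strip_size}"
        )
    out = np.zeros(image_shape, dtype=strip_mask.dtype)
    if not strip_mask.any():
        return out
    fwd = transform.forward_map()
    rows = np.clip(np.round(fwd[..., 0]).astype(int), 0, image_shape[0] - 1)
    cols = np.clip(np.round(fwd[..., 1]).astype(int), 0, image_shape[1] - 1)
    out[rows, cols] = strip_mask
    written = np.zeros(image_shape, dtype=bool)
    written[rows, cols] = True
    # rounding gaps are pixels a morphological closing of the written set
    # adds back (closing fills pinholes without moving the annulus rims);
    # each is filled from its nearest written pixel, which may carry label 0
    # — background stays background, so no label mixing
    closed = ndimage.binary_closing(written, structure=np.ones((3, 3)))
    fill = closed & ~written
    if fill.any():
        _, (ir, ic) = ndimage.distance_transform_edt(~written, return_indices=True)
        out[fill] = out[ir[fill], ic[fill]]
    return out


def _annulus_tree(transform: AnnulusTransform, row_step: int = 4):
    """KD-tree over forward-map samples (cached on the transform)."""
    if "tree" not in transform._maps:
        from scipy.spatial import cKDTree

        h = transform.height
        rows = np.unique(np.r_[np.arange(0, h, row_step), h - 1])
        fwd = transform.forward_map()[rows]  # (R, W, 2)
        pts = fwd.reshape(-1, 2)
        cols = np.broadcast_to(
            np.arange(transform.width)[None, :], fwd.shape[:2]
        ).ravel()
        transform._maps["tree"] = (cKDTree(pts), cols)
    return transform._maps["tree"]


def assign_dv_coordinate(
    centroid: tuple[float, float] | np.ndarray,
    transform: AnnulusTransform,
    midline: float = 0.0,
    tolerance: float = 4.0,
) -> float:
    """Signed DV fraction in (-1, 1] of an image-frame point.

    ``midline`` is the arc fraction (in [0, 1), measured from the transform's
    arc origin) of the dorsal midline.  Positive values are clockwise of the
    midline (right half for a top origin).  The arc column of the point is
    that of its nearest forward-map sample, which stays correct even where the
    annulus columns shear sideways with depth (the boundary normals of an
    elliptical outline are not radial).

    Raises OutsideAnnulusError if the point is farther than ``tolerance``
    pixels from every forward-map sample.
    """
    c = np.asarray(centroid, dtype=float)
    tree, cols = _annulus_tree(transform)
    dist, idx = tree.query(c)
    if dist > tolerance:
        raise OutsideAnnulusError(
            f"point {tuple(c)} outside annulus ({dist:.1f} px away)"
        )
    s = cols[idx] / transform.width
    d = ((s - midline + 0.5) % 1.0) - 0.5
    return 2.0 * d


def rasterize_annulus(
    transform: AnnulusTransform, image_shape: tuple[int, int]
) -> np.ndarray:
    """Boolean raster of the annulus region in image coordinates.

    Contours are subsampled before rasterization (polygon filling scales with
    vertex count); the boundary error is well under a pixel for the smooth
    splined contours used here.
    """
    step = max(1, transform.width // 360)
    outer = draw.polygon2mask(image_shape, transform.outer[::step])
    inner = draw.polygon2mask(image_shape, transform.inner[::step])
    return outer & ~inner
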