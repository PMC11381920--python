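"""Synthetic two-channel embryo images with complete ground truth.

Every downstream stage of the pipeline (unrolling, segmentation, gradient
fitting, normalization, averaging, spot calling, boundary estimation) is
exercised against images produced here, so the generator emulates the
features those stages depend on:

* an elliptical embryo outline with an annular layer of nuclei just under the
  surface (the blastoderm),
* a dorsoventral Gaussian signal gradient ``I(x) = B + A exp(-(x-mu)^2 /
  (2 sigma^2))`` over the signed DV coordinate ``x`` of each nucleus, which by
  default refines over time (broad and weak, then narrow and intense),
* nuclear enrichment of the signal over a cytoplasmic background (a
  configurable fraction of the local signal level),
* sub-nuclear bright dots of nascent transcripts planted inside a dorsal
  domain of half-width 0.27 DV (the broad Type III target-gene domain), at
  most one per nucleus per frame, placed in a single z-slice of the stack,
* control embryos whose reporter channel is spatially uniform background
  modulated by a slow oscillation (default period 9 min),
* a shared-field two-signal mode emulating fixed embryos co-stained for two
  readouts of one signaling field.

The DV coordinate of a synthetic nucleus is its arc-length fraction from the
dorsal midline (top of the image) along the elliptical outline, signed
clockwise-positive, matching the convention of :mod:`embryograd.geometry`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage

from .errors import ConfigurationError
from .series import EmbryoImageSeries


def gaussian_gradient(x, A, B, mu, sigma):
    """The Gaussian gradient model over the signed DV coordinate."""
    x = np.asarray(x, dtype=float)
    return B + A * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def refinement_trajectory(
    n_frames: int = 40,
    amplitude: tuple[float, float] = (2.0, 10.0),
    basal: float = 2.0,
    mu: float = 0.0,
    sigma: tuple[float, float] = (0.35, 0.12),
) -> list[tuple[float, float, float, float]]:
    """Default gradient time course: amplitude rises while width shrinks."""
    a = np.linspace(amplitude[0], amplitude[1], n_frames)
    s = np.linspace(sigma[0], sigma[1], n_frames)
    return [(float(a[i]), basal, mu, float(s[i])) for i in range(n_frames)]


class SyntheticConfig(BaseModel):
    """All parameters of the synthetic embryo generator.

    Geometric parameters are in micrometers and converted by ``pixel_size``;
    intensities are in detector counts (16-bit range).  ``gradient_trajectory``
    holds one (A, B, mu, sigma) tuple per frame in normalized intensity units;
    ``signal_gain`` converts those units to counts.
    """

    image_size: tuple[int, int] = (1024, 1024)
    pixel_size: float = 0.15  # um / pixel
    embryo_radii: tuple[float, float] = (70.0, 60.0)  # semi-axes (col, row), um
    nuclear_layer_depth: float = 18.36  # um, annulus depth used by unrolling
    n_nuclei: int = 80
    nucleus_radius: float = 2.2  # um
    nucleus_center_depth: float | None = None  # um inside outer boundary
    gradient_trajectory: list[tuple[float, float, float, float]] = Field(
        default_factory=refinement_trajectory
    )
    time_resolution: float = 30.0  # s / frame
    # imaging model
    nuclear_gain: float = 3000.0  # counts for a unit-brightness nucleus
    signal_gain: float = 300.0  # counts per normalized gradient unit
    background_counts: float = 80.0  # outside-embryo level
    cyto_fraction: float = 0.5  # cytoplasmic signal as fraction of local nuclear signal
    cyto_fraction_nuclear: float = 0.15
    edge_fraction: float = 0.15  # Gaussian edge width of the nucleus profile, x radius
    psf_sigma: float = 1.0  # px, single Gaussian blur
    noise_sigma: tuple[float, float] = (40.0, 40.0)  # additive counts (nuclear, signal)
    nucleus_cv: tuple[float, float] = (0.05, 0.05)  # per-nucleus multiplicative s.d.
    optical_ramp: float = 0.0  # DV-dependent attenuation applied to both channels
    # MS2 dots
    dot_domain_halfwidth: float = 0.27  # DV fraction (Type III broad domain)
    dot_probability: float = 0.8  # per domain nucleus per frame
    dot_contrast: float = 0.8  # dot peak amplitude as fraction of nuclear signal
    n_z: int = 12
    z_step: float = 2.0  # um
    # shared-field two-signal (fixed-embryo) mode
    channel_noise_frac: float = 0.2  # per-channel nucleus-wise multiplicative s.d.
    # control embryos
    oscillation_amplitude: float = 0.1  # fraction of the background level
    oscillation_period: float = 540.0  # s (9 min)
    control_level: float = 3.0  # background level, normalized units
    rng_seed: int = 0
    # recommended minimum component size (px) when segmenting these images;
    # None means the standard 400 px floor applies
    min_component_px: int | None = None

    @model_validator(mode="after")
    def _validate(self) -> "SyntheticConfig":
        for name in (
            "pixel_size",
            "nuclear_layer_depth",
            "nucleus_radius",
            "nuclear_gain",
            "signal_gain",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if min(self.embryo_radii) <= 0 or min(self.image_size) <= 0:
            raise ValueError("geometric parameters must be positive")
        if not 0.0 <= self.dot_domain_halfwidth <= 1.0:
            raise ValueError("dot_domain_halfwidth must be in [0, 1]")
        if not 0.0 <= self.dot_probability <= 1.0:
            raise ValueError("dot_probability must be in [0, 1]")
        if self.n_nuclei < 1 or self.n_z < 1:
            raise ValueError("n_nuclei and n_z must be at least 1")
        return self

    # ---- canonical study conditions -------------------------------------
    @classmethod
    def live_default(cls, n_frames: int = 40, **overrides) -> "SyntheticConfig":
        """Live gradient time course with the default refinement trajectory."""
        kw = dict(gradient_trajectory=refinement_trajectory(n_frames))
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def fixed_default(cls, **overrides) -> "SyntheticConfig":
        """Fixed-embryo cross-section: one frame, shared two-signal field.

        The per-channel nucleus-wise noise fraction (0.2) is set so that the
        expected Pearson correlation between the two channels across nuclei
        is ~0.9 for the default gradient (see docs/methods.md).
        """
        kw = dict(gradient_trajectory=[(10.0, 2.0, 0.0, 0.15)])
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def ms2_default(cls, n_frames: int = 5, **overrides) -> "SyntheticConfig":
        """MS2 z-stack time course: uniform MCP background plus planted dots.

        Rendered at 512x512 / 0.30 um px (half the linear scale of the live
        default) with a correspondingly scaled minimum component size; the
        full 12-slice stack is kept so that the dot-to-record fraction, which
        the percentile threshold depends on, matches the full-scale regime.
        """
        kw = dict(
            image_size=(512, 512),
            pixel_size=0.30,
            n_nuclei=70,
            gradient_trajectory=[(0.0, 4.0, 0.0, 0.15)] * n_frames,
            min_component_px=100,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def noiseless(cls, **overrides) -> "SyntheticConfig":
        """Idealized limit: hard-edged nuclei, no blur, no noise.

        Cytoplasmic fractions are equal in both channels so that per-nucleus
        signal/nuclear intensity ratios are exactly the generating gradient
        regardless of how tightly the segmentation mask hugs the nucleus.
        """
        kw = dict(
            noise_sigma=(0.0, 0.0),
            nucleus_cv=(0.0, 0.0),
            channel_noise_frac=0.0,
            edge_fraction=0.0,
            psf_sigma=0.0,
            cyto_fraction=0.5,
            cyto_fraction_nuclear=0.5,
        )
        kw.update(overrides)
        return cls(**kw)

    @property
    def n_frames(self) -> int:
        return len(self.gradient_trajectory)


@dataclass
class GroundTruth:
    """Generating truth for one synthetic embryo.

    ``nuclei`` holds the static per-nucleus geometry (id, row, col, dv,
    arc_fraction); ``values`` the per-frame rendered plateau intensities in
    counts (columns ``nuclear_value``, ``signal_value`` and, in shared-field
    mode, ``signal2_value``); ``dots`` one row per planted dot (frame, z,
    nucleus, row, col); ``true_gradient`` the (A, B, mu, sigma) trajectory in
    normalized units.
    """

    nuclei: pd.DataFrame
    values: pd.DataFrame
    true_gradient: pd.DataFrame
    dots: pd.DataFrame
    true_domain_halfwidth: float | None = None
    control_background: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(self.dots) and not set(self.dots["nucleus"]) <= set(self.nuclei["id"]):
            raise ValueError("dot nucleus id does not refer to an existing nucleus")
        dv = self.nuclei["dv"].to_numpy()
        if len(dv) and (dv.min() < -1.0 or dv.max() > 1.0):
            raise ValueError("DV coordinates must lie in [-1, 1]")

    def to_json(self, path) -> None:
        import json

        payload = {
            "nuclei": self.nuclei.to_dict(orient="list"),
            "values": self.values.to_dict(orient="list"),
            "true_gradient": self.true_gradient.to_dict(orient="list"),
            "dots": self.dots.to_dict(orient="list"),
            "true_domain_halfwidth": self.true_domain_halfwidth,
            "control_background": (
                None
                if self.control_background is None
                else self.control_background.to_dict(orient="list")
            ),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        import json

        with open(path) as fh:
            d = json.load(fh)
        return cls(
            nuclei=pd.DataFrame(d["nuclei"]),
            values=pd.DataFrame(d["values"]),
            true_gradient=pd.DataFrame(d["true_gradient"]),
            dots=pd.DataFrame(d["dots"], columns=["frame", "z", "nucleus", "row", "col"]),
            true_domain_halfwidth=d["true_domain_halfwidth"],
            control_background=(
                None
                if d["control_background"] is None
                else pd.DataFrame(d["control_background"])
            ),
        )


# ---------------------------------------------------------------------------
# analytic ellipse geometry
# ---------------------------------------------------------------------------


class _EllipseFrame:
    """Arc-length parameterization of the embryo outline, clockwise from top."""

    def __init__(self, cfg: SyntheticConfig):
        h, w = cfg.image_size
        self.center = (h / 2.0, w / 2.0)
        self.a = cfg.embryo_radii[0] / cfg.pixel_size  # column semi-axis, px
        self.b = cfg.embryo_radii[1] / cfg.pixel_size  # row semi-axis, px
        phi = np.linspace(0.0, 2.0 * np.pi, 8192, endpoint=False)
        col = self.a * np.sin(phi)
        row = -self.b * np.cos(phi)
        seg = np.hypot(np.diff(col, append=col[:1]), np.diff(row, append=row[:1]))
        arc = np.concatenate([[0.0], np.cumsum(seg)])[:-1]
        self.perimeter = arc[-1] + seg[-1]
        self._phi = phi
        self._frac_of_phi = arc / self.perimeter

    def phi_at_fraction(self, frac: np.ndarray) -> np.ndarray:
        return np.interp(np.mod(frac, 1.0), self._frac_of_phi, self._phi)

    def fraction_at_phi(self, phi: np.ndarray) -> np.ndarray:
        return np.interp(np.mod(phi, 2.0 * np.pi), self._phi, self._frac_of_phi)

    def point(self, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cy, cx = self.center
        return cy - self.b * np.cos(phi), cx + self.a * np.sin(phi)

    def inward_normal(self, phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        row_r = -self.b * np.cos(phi)
        col_r = self.a * np.sin(phi)
        nr, nc = row_r / self.b**2, col_r / self.a**2
        norm = np.hypot(nr, nc)
        return -nr / norm, -nc / norm

    def pixel_fields(
        self, shape: tuple[int, int]
    ) -> tuple[np.ndarray, np.ndarray]:
        """(inside mask, signed DV fraction per pixel) for the whole frame."""
        cy, cx = self.center
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        u = (cc - cx) / self.a
        v = (rr - cy) / self.b
        inside = u**2 + v**2 <= 1.0
        phi = np.mod(np.arctan2(u, -v), 2.0 * np.pi)
        frac = self.fraction_at_phi(phi)
        dv = np.where(frac <= 0.5, 2.0 * frac, 2.0 * frac - 2.0)
        return inside, dv


def _fold(frac: np.ndarray) -> np.ndarray:
    """Arc fraction in [0, 1) -> signed DV coordinate in (-1, 1]."""
    frac = np.mod(np.asarray(frac, dtype=float), 1.0)
    return np.where(frac <= 0.5, 2.0 * frac, 2.0 * frac - 2.0)


def _place_nuclei(cfg: SyntheticConfig, frame_geom: _EllipseFrame) -> pd.DataFrame:
    """Jittered equal-arc placement of nucleus centers inside the annulus."""
    r_px = cfg.nucleus_radius / cfg.pixel_size
    spacing = frame_geom.perimeter / cfg.n_nuclei
    if spacing < 2.2 * r_px:
        raise ConfigurationError(
            f"cannot place {cfg.n_nuclei} nuclei of radius {r_px:.1f} px without "
            f"overlap: arc spacing {spacing:.1f} px < {2.2 * r_px:.1f} px"
        )
    rng = np.random.default_rng([cfg.rng_seed, 0])
    jitter_px = 0.5 * (spacing - 2.2 * r_px)
    base = (np.arange(cfg.n_nuclei) + 0.5) / cfg.n_nuclei
    frac = base + rng.uniform(-1.0, 1.0, cfg.n_nuclei) * jitter_px / frame_geom.perimeter
    depth = cfg.nucleus_center_depth
    if depth is None:
        depth = 1.3 * cfg.nucleus_radius
    depth_px = depth / cfg.pixel_size
    phi = frame_geom.phi_at_fraction(frac)
    row_b, col_b = frame_geom.point(phi)
    nr, nc = frame_geom.inward_normal(phi)
    return pd.DataFrame(
        {
            "id": np.arange(cfg.n_nuclei),
            "row": row_b + depth_px * nr,
            "col": col_b + depth_px * nc,
            "arc_fraction": np.mod(frac, 1.0),
            "dv": _fold(frac),
        }
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _render_frame(
    cfg: SyntheticConfig,
    frame_geom: _EllipseFrame,
    nuclei: pd.DataFrame,
    channel_values: Sequence[np.ndarray],
    cyto_levels: Sequence[np.ndarray | float],
    fields: tuple[np.ndarray, np.ndarray] | None = None,
) -> list[np.ndarray]:
    """Render one noiseless, unblurred frame per channel (float canvases).

    ``channel_values[c][i]`` is the plateau intensity (counts) of nucleus i in
    channel c; ``cyto_levels[c]`` the cytoplasmic level, either a scalar or a
    per-pixel field over the whole frame.
    """
    shape = cfg.image_size
    if fields is None:
        fields = frame_geom.pixel_fields(shape)
    inside, _ = fields
    r_px = cfg.nucleus_radius / cfg.pixel_size
    edge = cfg.edge_fraction * r_px
    flat_r = max(r_px - 2.0 * edge, 0.0)
    pad = int(np.ceil(r_px + 3.0 * edge)) + 1
    canvases = []
    rows = nuclei["row"].to_numpy()
    cols = nuclei["col"].to_numpy()
    for values, cyto in zip(channel_values, cyto_levels):
        canvas = np.full(shape, cfg.background_counts, dtype=float)
        if np.isscalar(cyto):
            canvas[inside] = cyto
        else:
            canvas[inside] = cyto[inside]
        for i in range(len(nuclei)):
            r0, c0 = rows[i], cols[i]
            rlo, rhi = int(r0) - pad, int(r0) + pad + 1
            clo, chi = int(c0) - pad, int(c0) + pad + 1
            rlo, clo = max(rlo, 0), max(clo, 0)
            rhi, chi = min(rhi, shape[0]), min(chi, shape[1])
            pr, pc = np.mgrid[rlo:rhi, clo:chi]
            d = np.hypot(pr - r0, pc - c0)
            if edge == 0.0:
                disk = d <= r_px
                patch = canvas[rlo:rhi, clo:chi]
                patch[disk] = values[i]
            else:
                profile = np.exp(-np.maximum(d - flat_r, 0.0) ** 2 / (2.0 * edge**2))
                local_cyto = (
                    cyto if np.isscalar(cyto) else cyto[int(round(r0)), int(round(c0))]
                )
                canvas[rlo:rhi, clo:chi] += (values[i] - local_cyto) * profile
        canvases.append(canvas)
    return canvases


def _finalize(
    cfg: SyntheticConfig, canvas: np.ndarray, noise_sigma: float, rng
) -> np.ndarray:
    """Blur, add read noise, quantize to uint16."""
    out = canvas
    if cfg.psf_sigma > 0:
        out = ndimage.gaussian_filter(out, cfg.psf_sigma)
    if noise_sigma > 0:
        out = out + rng.normal(0.0, noise_sigma, out.shape)
    return np.clip(np.round(out), 0, 65535).astype(np.uint16)


def _nucleus_values(
    cfg: SyntheticConfig, nuclei: pd.DataFrame, params, eps_nuc, eps_sig
) -> tuple[np.ndarray, np.ndarray]:
    A, B, mu, sigma = params
    grad = gaussian_gradient(nuclei["dv"].to_numpy(), A, B, mu, sigma)
    u = cfg.nuclear_gain * (1.0 + cfg.nucleus_cv[0] * eps_nuc)
    v = cfg.signal_gain * grad * (1.0 + cfg.nucleus_cv[1] * eps_sig)
    return u, v


def _cyto_signal_field(
    cfg: SyntheticConfig, fields, params
) -> np.ndarray:
    """Per-pixel cytoplasmic signal level across the embryo interior."""
    A, B, mu, sigma = params
    _, dv = fields
    return cfg.cyto_fraction * cfg.signal_gain * gaussian_gradient(dv, A, B, mu, sigma)


def _apply_ramp(cfg, fields, canvases):
    if cfg.optical_ramp:
        inside, dv = fields
        factor = 1.0 + cfg.optical_ramp * np.abs(dv)
        for canvas in canvases:
            canvas[inside] *= factor[inside]


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------


def _static_draws(cfg: SyntheticConfig):
    """Per-embryo draws that are fixed across frames and slices."""
    rng = np.random.default_rng([cfg.rng_seed, 0, 1])
    eps_nuc = rng.standard_normal(cfg.n_nuclei)
    eps_sig = rng.standard_normal(cfg.n_nuclei)
    eps_ch2 = rng.standard_normal(cfg.n_nuclei)
    return eps_nuc, eps_sig, eps_ch2


def generate_cross_section(
    cfg: SyntheticConfig, frame_index: int = 0
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render one two-channel single-slice cross-section.

    Returns (nuclear image, signal image, ground truth) for the requested
    frame of the configured gradient trajectory.  Identical config and seed
    give bit-identical images.
    """
    if not 0 <= frame_index < cfg.n_frames:
        raise IndexError(
            f"frame_index {frame_index} outside trajectory of {cfg.n_frames}"
        )
    geom = _EllipseFrame(cfg)
    nuclei = _place_nuclei(cfg, geom)
    fields = geom.pixel_fields(cfg.image_size)
    eps_nuc, eps_sig, _ = _static_draws(cfg)
    params = cfg.gradient_trajectory[frame_index]
    u, v = _nucleus_values(cfg, nuclei, params, eps_nuc, eps_sig)
    canvases = _render_frame(
        cfg,
        geom,
        nuclei,
        [u, v],
        [cfg.cyto_fraction_nuclear * cfg.nuclear_gain, _cyto_signal_field(cfg, fields, params)],
        fields=fields,
    )
    _apply_ramp(cfg, fields, canvases)
    rng = np.random.default_rng([cfg.rng_seed, 1, frame_index, 0])
    nuc_img = _finalize(cfg, canvases[0], cfg.noise_sigma[0], rng)
    sig_img = _finalize(cfg, canvases[1], cfg.noise_sigma[1], rng)
    gt = _ground_truth(cfg, nuclei, [frame_index], {"nuclear_value": u, "signal_value": v})
    return nuc_img, sig_img, gt


def _ground_truth(cfg, nuclei, frames, per_frame_values, dots=None, control=None):
    """Assemble a GroundTruth from per-frame value-column dicts.

    ``per_frame_values`` maps frame index -> {column: per-nucleus array}, or
    is a single {column: array} dict applying to the only frame in ``frames``.
    """
    if not isinstance(next(iter(per_frame_values)), int):
        per_frame_values = {frames[0]: per_frame_values}
    values = pd.concat(
        [
            pd.DataFrame({"frame": f, "id": nuclei["id"], **cols})
            for f, cols in per_frame_values.items()
        ],
        ignore_index=True,
    )
    grad = pd.DataFrame(
        [
            {
                "frame": f,
                "A": cfg.gradient_trajectory[f][0],
                "B": cfg.gradient_trajectory[f][1],
                "mu": cfg.gradient_trajectory[f][2],
                "sigma": cfg.gradient_trajectory[f][3],
            }
            for f in frames
        ]
    )
    if dots is None:
        dots = pd.DataFrame(columns=["frame", "z", "nucleus", "row", "col"])
    return GroundTruth(
        nuclei=nuclei,
        values=values,
        true_gradient=grad,
        dots=dots,
        true_domain_halfwidth=cfg.dot_domain_halfwidth,
        control_background=control,
    )


def generate_time_course(
    cfg: SyntheticConfig,
) -> tuple[EmbryoImageSeries, GroundTruth]:
    """Render the full single-slice time course of the gradient trajectory."""
    if cfg.n_frames == 0:
        raise ConfigurationError("gradient_trajectory is empty")
    geom = _EllipseFrame(cfg)
    nuclei = _place_nuclei(cfg, geom)
    fields = geom.pixel_fields(cfg.image_size)
    eps_nuc, eps_sig, _ = _static_draws(cfg)
    h, w = cfg.image_size
    data = np.empty((cfg.n_frames, 2, 1, h, w), dtype=np.uint16)
    per_frame = {}
    for t, params in enumerate(cfg.gradient_trajectory):
        u, v = _nucleus_values(cfg, nuclei, params, eps_nuc, eps_sig)
        canvases = _render_frame(
            cfg,
            geom,
            nuclei,
            [u, v],
            [
                cfg.cyto_fraction_nuclear * cfg.nuclear_gain,
                _cyto_signal_field(cfg, fields, params),
            ],
            fields=fields,
        )
        _apply_ramp(cfg, fields, canvases)
        rng = np.random.default_rng([cfg.rng_seed, 1, t, 0])
        data[t, 0, 0] = _finalize(cfg, canvases[0], cfg.noise_sigma[0], rng)
        data[t, 1, 0] = _finalize(cfg, canvases[1], cfg.noise_sigma[1], rng)
        per_frame[t] = {"nuclear_value": u, "signal_value": v}
    series = EmbryoImageSeries(
        data, cfg.pixel_size, cfg.time_resolution, cfg.z_step
    )
    gt = _ground_truth(cfg, nuclei, list(range(cfg.n_frames)), per_frame)
    return series, gt


def generate_fixed_embryo(
    cfg: SyntheticConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Three-channel fixed-embryo cross-section from one shared signal field.

    Both signal channels render the same per-nucleus Gaussian field, each
    perturbed by independent nucleus-wise multiplicative noise of fraction
    ``channel_noise_frac`` — the generating model for the two-readout
    correlation benchmark.  Returns (nuclear, signal1, signal2, truth).
    """
    geom = _EllipseFrame(cfg)
    nuclei = _place_nuclei(cfg, geom)
    fields = geom.pixel_fields(cfg.image_size)
    eps_nuc, eps1, eps2 = _static_draws(cfg)
    params = cfg.gradient_trajectory[0]
    grad = gaussian_gradient(nuclei["dv"].to_numpy(), *params)
    f = cfg.channel_noise_frac
    u = cfg.nuclear_gain * (1.0 + cfg.nucleus_cv[0] * eps_nuc)
    v1 = cfg.signal_gain * grad * (1.0 + f * eps1)
    v2 = cfg.signal_gain * grad * (1.0 + f * eps2)
    cyto = _cyto_signal_field(cfg, fields, params)
    canvases = _render_frame(
        cfg,
        geom,
        nuclei,
        [u, v1, v2],
        [cfg.cyto_fraction_nuclear * cfg.nuclear_gain, cyto, cyto],
        fields=fields,
    )
    _apply_ramp(cfg, fields, canvases)
    rng = np.random.default_rng([cfg.rng_seed, 1, 0, 0])
    nuc = _finalize(cfg, canvases[0], cfg.noise_sigma[0], rng)
    ch1 = _finalize(cfg, canvases[1], cfg.noise_sigma[1], rng)
    ch2 = _finalize(cfg, canvases[2], cfg.noise_sigma[1], rng)
    gt = _ground_truth(
        cfg,
        nuclei,
        [0],
        {"nuclear_value": u, "signal_value": v1, "signal2_value": v2},
    )
    return nuc, ch1, ch2, gt


def generate_ms2_stack(cfg: SyntheticConfig) -> tuple[EmbryoImageSeries, GroundTruth]:
    """Render a z-stacked MS2 time course with planted nascent-transcript dots.

    Each nucleus spans the whole (short) z-range and yields one segmentation
    record per slice; a dot-bearing nucleus carries its dot in exactly one
    slice per frame, so the dot-positive fraction of records is
    ``dot_probability * dot_domain_halfwidth / n_z`` — the regime in which a
    98th-percentile score threshold isolates genuine transcription dots.
    """
    geom = _EllipseFrame(cfg)
    nuclei = _place_nuclei(cfg, geom)
    fields = geom.pixel_fields(cfg.image_size)
    eps_nuc, eps_sig, _ = _static_draws(cfg)
    r_px = cfg.nucleus_radius / cfg.pixel_size
    offset = 0.35 * r_px
    h, w = cfg.image_size
    data = np.empty((cfg.n_frames, 2, cfg.n_z, h, w), dtype=np.uint16)
    dots_rows = []
    per_frame = {}
    in_domain = np.abs(nuclei["dv"].to_numpy()) <= cfg.dot_domain_halfwidth
    for t, params in enumerate(cfg.gradient_trajectory):
        u, v = _nucleus_values(cfg, nuclei, params, eps_nuc, eps_sig)
        base = _render_frame(
            cfg,
            geom,
            nuclei,
            [u, v],
            [
                cfg.cyto_fraction_nuclear * cfg.nuclear_gain,
                _cyto_signal_field(cfg, fields, params),
            ],
            fields=fields,
        )
        _apply_ramp(cfg, fields, base)
        rng_dots = np.random.default_rng([cfg.rng_seed, 2, t])
        has_dot = in_domain & (rng_dots.uniform(size=cfg.n_nuclei) < cfg.dot_probability)
        dot_z = rng_dots.integers(0, cfg.n_z, cfg.n_nuclei)
        for z in range(cfg.n_z):
            sig = base[1].copy()
            for i in np.flatnonzero(has_dot & (dot_z == z)):
                r0 = int(round(nuclei["row"].iloc[i] + offset))
                c0 = int(round(nuclei["col"].iloc[i] + offset))
                amp = cfg.dot_contrast * v[i]
                sig[r0 - 1 : r0 + 2, c0 - 1 : c0 + 2] += 0.6 * amp
                sig[r0, c0] += 0.4 * amp
                dots_rows.append(
                    {"frame": t, "z": z, "nucleus": int(nuclei["id"].iloc[i]),
                     "row": r0, "col": c0}
                )
            rng = np.random.default_rng([cfg.rng_seed, 1, t, z])
            data[t, 0, z] = _finalize(cfg, base[0], cfg.noise_sigma[0], rng)
            data[t, 1, z] = _finalize(cfg, sig, cfg.noise_sigma[1], rng)
        per_frame[t] = {"nuclear_value": u, "signal_value": v}
    series = EmbryoImageSeries(
        data, cfg.pixel_size, cfg.time_resolution, cfg.z_step
    )
    dots = pd.DataFrame(dots_rows, columns=["frame", "z", "nucleus", "row", "col"])
    gt = _ground_truth(cfg, nuclei, list(range(cfg.n_frames)), per_frame, dots=dots)
    return series, gt


def generate_control_embryo(
    cfg: SyntheticConfig,
) -> tuple[EmbryoImageSeries, GroundTruth]:
    """Control embryo: nuclear channel as usual, reporter channel background.

    The signal channel carries no gradient and no nuclear enrichment — only a
    spatially uniform level modulated in time by the configured oscillation
    (default period 9 min), emulating the unexplained slow intensity
    fluctuations seen in no-reporter controls.
    """
    geom = _EllipseFrame(cfg)
    nuclei = _place_nuclei(cfg, geom)
    fields = geom.pixel_fields(cfg.image_size)
    eps_nuc, _, _ = _static_draws(cfg)
    h, w = cfg.image_size
    n_frames = cfg.n_frames
    data = np.empty((n_frames, 2, 1, h, w), dtype=np.uint16)
    times = np.arange(n_frames) * cfg.time_resolution
    levels = (
        cfg.signal_gain
        * cfg.control_level
        * (1.0 + cfg.oscillation_amplitude * np.sin(2.0 * np.pi * times / cfg.oscillation_period))
    )
    u = cfg.nuclear_gain * (1.0 + cfg.nucleus_cv[0] * eps_nuc)
    per_frame = {}
    inside, _ = fields
    for t in range(n_frames):
        v = np.full(cfg.n_nuclei, levels[t])
        canvases = _render_frame(
            cfg,
            geom,
            nuclei,
            [u, v],
            [cfg.cyto_fraction_nuclear * cfg.nuclear_gain, levels[t]],
            fields=fields,
        )
        rng = np.random.default_rng([cfg.rng_seed, 1, t, 0])
        data[t, 0, 0] = _finalize(cfg, canvases[0], cfg.noise_sigma[0], rng)
        data[t, 1, 0] = _finalize(cfg, canvases[1], cfg.noise_sigma[1], rng)
        per_frame[t] = {"nuclear_value": u, "signal_value": v}
    series = EmbryoImageSeries(
        data, cfg.pixel_size, cfg.time_resolution, cfg.z_step
    )
    control = pd.DataFrame({"frame": np.arange(n_frames), "time": times, "level": levels})
    gt = _ground_truth(cfg, nuclei, list(range(n_frames)), per_frame, control=control)
    return series, gt
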