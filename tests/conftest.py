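"""Shared fixtures: small synthetic embryos analyzed once per session."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from embryograd import geometry, segmentation, synth

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

# reduced-geometry study conditions used by fast unit tests: half the embryo
# sampling of the full-scale default, same physical dimensions
SMALL = dict(image_size=(384, 384), pixel_size=0.4, n_nuclei=50)
SMALL_MIN_SIZE = 50


def small_noiseless_config(**overrides):
    kw = dict(gradient_trajectory=[(10.0, 2.0, 0.0, 0.15)], **SMALL)
    kw.update(overrides)
    return synth.SyntheticConfig.noiseless(**kw)


def analyze_frame(nuc, sig, cfg, min_size=SMALL_MIN_SIZE, extra=None):
    """Boundary -> annulus -> segment -> records, for one cross-section."""
    outer = geometry.detect_embryo_boundary(nuc)
    transform = geometry.annulus_transform(outer, cfg.nuclear_layer_depth, cfg.pixel_size)
    strip = geometry.unroll(nuc, transform)
    labels = segmentation.segment_strip(strip, min_size=min_size)
    img_labels = geometry.map_mask_back(labels, transform, nuc.shape)
    records = segmentation.extract_nuclei(
        img_labels, nuc, sig, transform, extra_channels=extra
    )
    return records, transform, img_labels


@pytest.fixture(scope="session")
def small_noiseless():
    cfg = small_noiseless_config()
    nuc, sig, gt = synth.generate_cross_section(cfg, 0)
    return cfg, nuc, sig, gt


@pytest.fixture(scope="session")
def small_noiseless_records(small_noiseless):
    cfg, nuc, sig, gt = small_noiseless
    records, transform, labels = analyze_frame(nuc, sig, cfg)
    return cfg, gt, records, transform, labels


@pytest.fixture(scope="session")
def full_noiseless():
    """Full-scale noiseless frame: the idealized round-trip condition."""
    cfg = synth.SyntheticConfig.noiseless(
        gradient_trajectory=[(10.0, 2.0, 0.0, 0.15)]
    )
    nuc, sig, gt = synth.generate_cross_section(cfg, 0)
    records, transform, labels = analyze_frame(nuc, sig, cfg, min_size=400)
    return cfg, gt, records


@pytest.fixture(scope="session")
def default_frame():
    """Full-scale default synthetic frame (with noise) and its analysis."""
    cfg = synth.SyntheticConfig.live_default(n_frames=1)
    nuc, sig, gt = synth.generate_cross_section(cfg, 0)
    records, transform, labels = analyze_frame(nuc, sig, cfg, min_size=400)
    return cfg, gt, records


@pytest.fixture(scope="session")
def small_ms2():
    """Small MS2 z-stack time course plus its full spot/boundary analysis."""
    from embryograd import pipeline

    # n_z keeps the dot-positive record fraction (p * halfwidth / n_z) below
    # the 2% threshold tail, as in the full-scale acquisition geometry
    cfg = synth.SyntheticConfig(
        image_size=(256, 256),
        pixel_size=0.6,
        n_nuclei=30,
        gradient_trajectory=[(0.0, 4.0, 0.0, 0.15)] * 6,
        n_z=11,
        min_component_px=25,
        rng_seed=7,
    )
    series, gt = synth.generate_ms2_stack(cfg)
    result = pipeline.ms2_domain_analysis(series, min_size=cfg.min_component_px)
    return cfg, gt, series, result


def circle_contour(center, radius, n=720):
    """Analytic circular contour (row, col), clockwise from the top."""
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.stack(
        [center[0] - radius * np.cos(theta), center[1] + radius * np.sin(theta)],
        axis=1,
    )


def match_to_truth(records, gt, max_dist):
    """Nearest-centroid matching of records to ground-truth nuclei."""
    from scipy.spatial import cKDTree

    pts = gt.nuclei[["row", "col"]].to_numpy()
    d, idx = cKDTree(pts).query(records[["row", "col"]].to_numpy())
    ok = d < max_dist
    return d, idx, ok
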