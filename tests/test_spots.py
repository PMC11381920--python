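"""Dot scoring, percentile calling and the penalized boundary statistic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from embryograd import spots
from embryograd.errors import NucleusTooSmallError
from embryograd.spots import (
    boundary_score,
    call_dots,
    find_boundaries,
    find_boundary,
    score_nucleus,
    width_time_course,
)


def enumerate_seven_by_seven():
    """Hand-enumerated oracle: 7x7 nucleus, background 10, one pixel 110.

    The 5x5 block centered on the max is removed; the 24 remaining pixels all
    carry the background value.
    """
    pix = np.full((7, 7), 10.0)
    pix[3, 3] = 110.0
    i_max = -np.inf
    pos = None
    for r in range(7):
        for c in range(7):
            if pix[r, c] > i_max:
                i_max, pos = pix[r, c], (r, c)
    rest = []
    for r in range(7):
        for c in range(7):
            if abs(r - pos[0]) > 2 or abs(c - pos[1]) > 2:
                rest.append(pix[r, c])
    return i_max, float(np.mean(rest)), len(rest)


class TestScore:
    def test_seven_by_seven_oracle(self):
        i_max, i_mean, n_rest = enumerate_seven_by_seven()
        assert n_rest == 24 and i_mean == 10.0
        record = {
            "max_signal": i_max,
            "mean_signal_minus_spot": i_mean,
            "mean_nuclear": 50.0,
        }
        assert score_nucleus(record) == pytest.approx(2.0)

    def test_extraction_matches_the_oracle(self):
        # run the same nucleus through the real extraction path
        from embryograd import geometry, segmentation
        from conftest import circle_contour

        outer = circle_contour((80, 80), 60)
        tr = geometry.annulus_transform(outer, depth=30.0, pixel_size=1.0)
        labels = np.zeros((160, 160), dtype=np.int32)
        labels[20:27, 77:84] = 1  # a 7x7 nucleus inside the annulus
        signal = np.full((160, 160), 10.0)
        signal[23, 80] = 110.0
        nuclear = np.full((160, 160), 50.0)
        rec = segmentation.extract_nuclei(labels, nuclear, signal, tr)
        assert len(rec) == 1
        assert rec.max_signal.iloc[0] == 110.0
        assert rec.mean_signal_minus_spot.iloc[0] == pytest.approx(10.0)
        assert score_nucleus(rec.iloc[0]) == pytest.approx(2.0)

    def test_uniform_nucleus_scores_zero(self):
        rec = {"max_signal": 7.0, "mean_signal_minus_spot": 7.0, "mean_nuclear": 3.0}
        assert score_nucleus(rec) == 0.0

    def test_emptied_nucleus_raises(self):
        rec = {"max_signal": 7.0, "mean_signal_minus_spot": np.nan, "mean_nuclear": 3.0}
        with pytest.raises(NucleusTooSmallError):
            score_nucleus(rec)

    def test_score_increases_with_planted_contrast(self):
        from embryograd import synth, pipeline

        means = []
        for contrast in (0.3, 0.6, 0.9):
            cfg = synth.SyntheticConfig(
                image_size=(256, 256), pixel_size=0.6, n_nuclei=30, n_z=2,
                gradient_trajectory=[(0.0, 4.0, 0.0, 0.15)],
                dot_probability=1.0, dot_contrast=contrast,
                min_component_px=25, rng_seed=5,
            )
            series, gt = synth.generate_ms2_stack(cfg)
            res = pipeline.ms2_domain_analysis(series, min_size=25)
            calls = res.calls
            dot_scores = []
            for _, d in gt.dots.iterrows():
                sel = calls[(calls.frame == d.frame) & (calls.z == d.z)]
                dist = np.hypot(sel.row - d.row, sel.col - d.col)
                if dist.min() < 8:
                    dot_scores.append(sel.S.iloc[int(np.argmin(dist.to_numpy()))])
            means.append(np.mean(dot_scores))
        assert means[0] < means[1] < means[2]


class TestCallDots:
    def test_distinct_scores_top_two_percent(self):
        df = pd.DataFrame({"S": np.arange(100, dtype=float) / 100,
                           "frame": 0})
        out = call_dots(df)
        assert out.is_dot.sum() == 2
        assert set(np.flatnonzero(out.is_dot.to_numpy())) == {98, 99}

    def test_identical_scores_degenerate_all_called(self):
        df = pd.DataFrame({"S": np.full(60, 0.5), "frame": 0})
        out = call_dots(df)
        assert out.is_dot.all()
        assert out.degenerate_threshold.all()

    def test_few_records_warn(self):
        df = pd.DataFrame({"S": np.arange(10, dtype=float), "frame": 0})
        with pytest.warns(UserWarning):
            call_dots(df)

    def test_threshold_recomputed_per_time_point(self, small_ms2):
        _, _, _, result = small_ms2
        thr = result.calls.groupby("frame").threshold_value.first()
        assert thr.nunique() > 1

    def test_called_records_are_planted_dots(self):
        from embryograd import synth, pipeline

        cfg = synth.SyntheticConfig(
            image_size=(256, 256), pixel_size=0.6, n_nuclei=30, n_z=6,
            gradient_trajectory=[(0.0, 4.0, 0.0, 0.15)] * 2,
            dot_probability=1.0, min_component_px=25, rng_seed=9,
        )
        series, gt = synth.generate_ms2_stack(cfg)
        res = pipeline.ms2_domain_analysis(series, min_size=25)
        called = res.calls[res.calls.is_dot]
        hits = 0
        for _, c in called.iterrows():
            d = gt.dots[(gt.dots.frame == c.frame) & (gt.dots.z == c.z)]
            if len(d) and np.hypot(d.row - c.row, d.col - c.col).min() < 8:
                hits += 1
        assert hits / len(called) >= 0.9


class TestBoundaryScore:
    def test_hand_enumerated_example(self):
        x = np.array([0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50])
        dots = np.zeros(10, dtype=bool)
        dots[:3] = True  # three most dorsal nuclei transcribe
        assert boundary_score(x, dots, 0.15) == pytest.approx(3.00)
        assert boundary_score(x, dots, 0.50) == pytest.approx(3 - 0.02 * 7)
        assert boundary_score(x, dots, 0.50) == pytest.approx(2.86)

    def test_no_dots_score_nonpositive(self):
        x = np.linspace(0, 1, 20)
        assert boundary_score(x, np.zeros(20, bool), 0.6) == pytest.approx(
            -0.02 * np.sum(x <= 0.6)
        )

    def test_all_dots_score_counts_dorsal(self):
        x = np.linspace(0, 1, 20)
        assert boundary_score(x, np.ones(20, bool), 1.0) == 20.0

    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=40),
        st.data(),
    )
    def test_argmax_matches_exhaustive_enumeration(self, xs, data):
        x = np.array(xs)
        dots = np.array(data.draw(
            st.lists(st.booleans(), min_size=len(xs), max_size=len(xs))
        ))
        calls = pd.DataFrame({"dv": x, "is_dot": dots, "frame": 0})
        b = find_boundary(calls)
        if dots.any():
            brute = {x0: boundary_score(x, dots, x0) for x0 in np.unique(x)}
            best_score = max(brute.values())
            expected = min(x0 for x0, s in brute.items() if s == best_score)
            assert b.right_boundary == pytest.approx(expected)
        else:
            assert b.right_boundary == 0.0 and b.right_empty

    def test_adding_a_dorsal_dot_changes_score_by_one(self):
        x = np.linspace(0, 1, 10)
        dots = np.zeros(10, bool)
        dots[2] = True
        s0 = boundary_score(x, dots, 0.5)
        x2 = np.append(x, 0.3)
        s_dot = boundary_score(x2, np.append(dots, True), 0.5)
        s_non = boundary_score(x2, np.append(dots, False), 0.5)
        assert s_dot - s0 == pytest.approx(1.0)
        assert s_non - s0 == pytest.approx(-0.02)


class TestFindBoundary:
    def _toy_calls(self):
        x = np.array([0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50])
        dots = np.zeros(10, dtype=bool)
        dots[:3] = True
        left = pd.DataFrame({"dv": -x, "is_dot": dots})
        right = pd.DataFrame({"dv": x, "is_dot": dots})
        df = pd.concat([left, right], ignore_index=True)
        df["frame"] = 0
        return df

    def test_toy_boundary_both_halves(self):
        b = find_boundary(self._toy_calls())
        assert b.left_boundary == pytest.approx(0.15)
        assert b.right_boundary == pytest.approx(0.15)
        assert b.width == pytest.approx(0.15)

    def test_gamma_zero_most_ventral_dot(self):
        x = np.array([0.1, 0.12, 0.14, 0.3, 0.5, 0.8, 0.9])
        dots = np.array([True, True, True, False, False, True, False])
        calls = pd.DataFrame({"dv": x, "is_dot": dots, "frame": 0})
        b = find_boundary(calls, gamma=0.0)
        assert b.right_boundary == pytest.approx(0.8)

    def test_gamma_near_one_stops_at_dorsal_run(self):
        x = np.array([0.1, 0.12, 0.14, 0.3, 0.5, 0.8, 0.9])
        dots = np.array([True, True, True, False, False, True, False])
        calls = pd.DataFrame({"dv": x, "is_dot": dots, "frame": 0})
        b = find_boundary(calls, gamma=0.999)
        assert b.right_boundary == pytest.approx(0.14)

    def test_empty_half_flagged_zero(self):
        calls = pd.DataFrame(
            {"dv": [0.2, 0.4, -0.3], "is_dot": [True, False, False], "frame": 0}
        )
        b = find_boundary(calls)
        assert b.left_empty and b.left_boundary == 0.0
        assert not b.right_empty

    def test_midline_insensitivity_on_synthetic_stack(self, small_ms2):
        cfg, _, _, result = small_ms2
        spacing = 2.0 / cfg.n_nuclei  # one nucleus spacing in DV units
        base = result.boundaries.width.mean()
        for shift in (-3 * spacing, 3 * spacing):
            shifted = find_boundaries(result.calls, midline_offset=shift)
            assert abs(shifted.width.mean() - base) < spacing

    def test_width_recovered_near_truth(self, small_ms2):
        cfg, gt, _, result = small_ms2
        assert result.summary["mean_width"] == pytest.approx(
            cfg.dot_domain_halfwidth, abs=0.07
        )

    def test_no_systematic_width_trend_on_stationary_stack(self, small_ms2):
        from scipy import stats as sstats

        _, _, _, result = small_ms2
        w = result.boundaries.sort_values("frame").width.to_numpy()
        res = sstats.linregress(np.arange(len(w)), w)
        # slope CI contains zero: stationary generator, stationary estimate
        ci = 2.78 * res.stderr  # t(0.975, df=4)
        assert abs(res.slope) <= ci


class TestWidthTimeCourse:
    def test_constant_widths(self):
        b = pd.DataFrame({"frame": range(5), "width": [0.25] * 5})
        out = width_time_course(b)
        assert out["mean_width"] == 0.25 and out["sd_width"] == 0.0

    def test_two_frame_hand_arithmetic(self):
        b = pd.DataFrame({"frame": [0, 1], "width": [0.2, 0.3]})
        out = width_time_course(b)
        assert out["mean_width"] == pytest.approx(0.25)
        assert out["sd_width"] == pytest.approx(0.0707, abs=1e-3)

    def test_ensemble_summary(self):
        per_embryo = [{"mean_width": w} for w in (0.2, 0.25, 0.3)]
        out = spots.ensemble_width_summary(per_embryo)
        assert out["mean_width"] == pytest.approx(0.25)
        assert out["n_embryos"] == 3

    def test_midline_estimate_centers_on_dot_cluster(self):
        rng = np.random.default_rng(1)
        dots = pd.DataFrame(
            {"dv": np.clip(rng.normal(0.1, 0.05, 50), -1, 1), "is_dot": True}
        )
        nondots = pd.DataFrame({"dv": rng.uniform(-1, 1, 100), "is_dot": False})
        offset = spots.estimate_midline_offset(pd.concat([dots, nondots]))
        assert offset == pytest.approx(0.1, abs=0.05)
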