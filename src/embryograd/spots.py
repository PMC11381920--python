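"""Nascent-transcript dot calling and expression-domain boundary estimation.

Each segmented nucleus record (one per nucleus per z-slice per time point)
receives a dot score

    S = (I_max - I_mean) / I_nuc

where I_max is the brightest reporter pixel in the nucleus, I_mean the
reporter mean after removing the 5x5 neighborhood of that pixel, and I_nuc
the nuclear-channel mean.  Per time point, records with S at or above the
98th percentile (theta = 0.98) over all z-slices are called dot-positive.

The expression-domain boundary on each half of the embryo maximizes the
penalized dorsal count

    score(x0) = #{dots with x <= x0} - gamma * #{non-dots with x <= x0}

over folded DV coordinates x in [0, 1], with gamma = 1 - theta = 0.02.  The
domain width of a frame is the average of the two halves' boundaries, which
makes the exact dorsal-midline position immaterial; a time course is
summarized as mean +/- s.d. of the per-frame widths.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NucleusTooSmallError

log = logging.getLogger(__name__)

THETA = 0.98
GAMMA = 1.0 - THETA


def score_nucleus(record) -> float:
    """Dot score S = (I_max - I_mean) / I_nuc of one nucleus record.

    ``record`` is any mapping with ``max_signal``, ``mean_signal_minus_spot``
    and ``mean_nuclear`` (a NucleusRecord, DataFrame row, or dict).

    Raises NucleusTooSmallError if removing the 5x5 spot neighborhood emptied
    the nucleus (``mean_signal_minus_spot`` is NaN).
    """
    i_max = record["max_signal"] if not hasattr(record, "max_signal") else record.max_signal
    i_mean = (
        record["mean_signal_minus_spot"]
        if not hasattr(record, "mean_signal_minus_spot")
        else record.mean_signal_minus_spot
    )
    i_nuc = record["mean_nuclear"] if not hasattr(record, "mean_nuclear") else record.mean_nuclear
    if not np.isfinite(i_mean):
        raise NucleusTooSmallError(
            "nucleus too small: 5x5 spot removal left no pixels"
        )
    return float((i_max - i_mean) / i_nuc)


def score_records(records: pd.DataFrame) -> pd.DataFrame:
    """Vectorized dot scores; adds an ``S`` column (NaN-rows dropped, logged)."""
    out = records.copy()
    out["S"] = (out["max_signal"] - out["mean_signal_minus_spot"]) / out["mean_nuclear"]
    bad = ~np.isfinite(out["S"])
    if bad.any():
        log.info("dropping %d records too small to score", int(bad.sum()))
        out = out.loc[~bad].copy()
    return out


def call_dots(records: pd.DataFrame, theta: float = THETA) -> pd.DataFrame:
    """Percentile-threshold dot calls for one time point (all z pooled).

    The threshold is the ``theta`` quantile (linear interpolation between
    order statistics) of S over every record of the time point; records with
    S >= threshold are dot-positive.  Adds ``is_dot`` and ``threshold_value``
    columns.  With fewer than 50 records the percentile is unstable (warns);
    identical scores everywhere make the call degenerate (all positive,
    flagged in the ``degenerate_threshold`` column).
    """
    out = records if "S" in records.columns else score_records(records)
    out = out.copy()
    if len(out) < 50:
        warnings.warn(
            f"only {len(out)} records at this time point; "
            "percentile threshold is unstable",
            stacklevel=2,
        )
    s = out["S"].to_numpy()
    thr = float(np.quantile(s, theta))
    out["threshold_value"] = thr
    out["is_dot"] = s >= thr
    out["degenerate_threshold"] = bool(np.all(s == s[0])) if s.size else False
    return out


def boundary_score(
    x: np.ndarray, is_dot: np.ndarray, x0: float, gamma: float = GAMMA
) -> float:
    """Penalized dorsal count at candidate boundary x0 (folded coordinates).

    score(x0) = #{dots with x <= x0} - gamma * #{non-dots with x <= x0}.
    """
    x = np.asarray(x, dtype=float)
    is_dot = np.asarray(is_dot, dtype=bool)
    dorsal = x <= x0
    return float(np.sum(dorsal & is_dot) - gamma * np.sum(dorsal & ~is_dot))


def _half_boundary(
    x: np.ndarray, is_dot: np.ndarray, gamma: float
) -> tuple[float, np.ndarray, bool]:
    """Argmax of the boundary score over observed nucleus positions.

    The score is piecewise constant between nucleus positions, so candidates
    are restricted to them; ties break toward the more dorsal (smaller) x0.
    A half with no dots has an empty domain: boundary 0, flagged.
    """
    if not is_dot.any():
        return 0.0, np.zeros(0), True
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ds = is_dot[order]
    # cumulative score at each candidate, honoring ties in x (same x0 ->
    # same score, so evaluate at unique positions)
    inc = np.where(ds, 1.0, -gamma)
    cum = np.cumsum(inc)
    uniq_x = np.unique(xs)
    last = np.searchsorted(xs, uniq_x, side="right") - 1
    scores = cum[last]
    best = int(np.argmax(scores))  # first max -> smallest x0 on ties
    return float(uniq_x[best]), scores, False


@dataclass
class DomainBoundary:
    """Per-frame left/right expression-domain boundaries (folded DV)."""

    frame: int
    left_boundary: float
    right_boundary: float
    width: float
    left_empty: bool = False
    right_empty: bool = False

    def as_dict(self) -> dict:
        return {
            "frame": self.frame,
            "left_boundary": self.left_boundary,
            "right_boundary": self.right_boundary,
            "width": self.width,
            "left_empty": self.left_empty,
            "right_empty": self.right_empty,
        }


def find_boundary(
    calls: pd.DataFrame,
    gamma: float = GAMMA,
    midline_offset: float = 0.0,
    frame: int | None = None,
) -> DomainBoundary:
    """Expression-domain boundary of one frame from its dot calls.

    ``calls`` carries signed DV coordinates (``dv``) and ``is_dot``;
    ``midline_offset`` shifts the assumed dorsal midline (signed DV units)
    before splitting into halves.  Each half's boundary maximizes the
    penalized score over its folded coordinates; the frame's width is the
    average of the two.
    """
    dv = calls["dv"].to_numpy(dtype=float) - midline_offset
    dv = (dv + 1.0) % 2.0 - 1.0
    dv[dv == -1.0] = 1.0  # keep the ventral midline at +1, not -1
    is_dot = calls["is_dot"].to_numpy(dtype=bool)
    left = dv < 0
    lb, _, l_empty = _half_boundary(-dv[left], is_dot[left], gamma)
    rb, _, r_empty = _half_boundary(dv[~left], is_dot[~left], gamma)
    if frame is None:
        frame = int(calls["frame"].iloc[0]) if "frame" in calls.columns else 0
    return DomainBoundary(
        frame=frame,
        left_boundary=lb,
        right_boundary=rb,
        width=0.5 * (lb + rb),
        left_empty=l_empty,
        right_empty=r_empty,
    )


def find_boundaries(
    calls: pd.DataFrame, gamma: float = GAMMA, midline_offset: float = 0.0
) -> pd.DataFrame:
    """Per-frame boundaries over a whole time course of dot calls."""
    rows = [
        find_boundary(group, gamma, midline_offset, frame=int(f)).as_dict()
        for f, group in calls.groupby("frame")
    ]
    return pd.DataFrame(rows)


def width_time_course(boundaries: pd.DataFrame) -> dict:
    """Mean and sample s.d. of the per-frame domain widths of one embryo."""
    w = boundaries["width"].to_numpy(dtype=float)
    return {
        "mean_width": float(np.mean(w)),
        "sd_width": float(np.std(w, ddof=1)) if w.size > 1 else 0.0,
        "n_frames": int(w.size),
    }


def ensemble_width_summary(per_embryo: list[dict]) -> dict:
    """Across-embryo summary of per-time-course mean widths (+/- s.e.m.)."""
    means = np.array([d["mean_width"] for d in per_embryo], dtype=float)
    return {
        "mean_width": float(means.mean()),
        "sem_width": float(means.std(ddof=1) / np.sqrt(len(means)))
        if len(means) > 1
        else 0.0,
        "n_embryos": int(len(means)),
        "per_embryo_mean": means.tolist(),
    }


def estimate_midline_offset(calls: pd.DataFrame) -> float:
    """Automatic dorsal-midline refinement: circular median of dot positions.

    Dot DV coordinates are mapped to angles on the unit circle; the circular
    median (the dot minimizing total circular distance to the others) gives a
    robust center of the dot cluster.  Returns the offset in signed DV units;
    0 if there are no dots.
    """
    dots = calls.loc[calls["is_dot"], "dv"].to_numpy(dtype=float)
    if dots.size == 0:
        return 0.0
    ang = dots * np.pi
    diff = np.abs(ang[:, None] - ang[None, :])
    diff = np.minimum(diff, 2.0 * np.pi - diff)
    return float(ang[np.argmin(diff.sum(axis=1))] / np.pi)
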