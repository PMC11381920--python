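"""Gaussian gradient fitting, normalization, and multi-embryo averaging.

Nuclear signal intensity versus signed DV coordinate x is modeled as

    I(x) = A * exp(-(x - mu)^2 / (2 sigma^2)) + B

with amplitude A, basal level B, peak location mu and gradient width sigma.
Three multiplicative normalizations make live intensities comparable:

* ``session_factor`` (Calib_norm): laser calibration per imaging session,
  Calib_norm = (Calib_mean / 1.74e4) * (0.1 / Calib_LP);
* ``timecourse_factor`` (timecourse_norm): per-embryo brightness,
  timecourse_norm = nuc_mean / (100 * nuc_LP);
* ``dv_norm_curve`` (curve_norm): DV-dependent attenuation estimated from the
  nuclear channel on a 151-point grid over the folded axis.

The constants 1.74e4, 0.1 and 100 put each factor close to 1 for a typical
session, so normalized intensities remain in familiar count-like units.

Multi-embryo averaging first smooths each embryo's fitted (A, B, sigma) over
time (10-frame window), averages them into ensemble parameters, rescales each
embryo's DV axis by chi_k(t) = sigma_bar(t)/sigma_k(t) so all gradients share
the ensemble width, pools the affinely normalized intensities, de-normalizes
with the ensemble parameters, folds left/right and bins onto a 36-point mesh
(spacing dx = 1/35) with half-width edge bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import AlignmentError, FitError
from .synth import gaussian_gradient

log = logging.getLogger(__name__)

CALIB_REFERENCE_MEAN = 1.74e4
CALIB_REFERENCE_LP = 0.1
TIMECOURSE_REFERENCE = 100.0
DV_GRID_POINTS = 151
MESH_POINTS = 36


@dataclass
class GradientFit:
    """Per-frame Gaussian gradient parameters with fit diagnostics."""

    A: float
    B: float
    mu: float
    sigma: float
    residual_norm: float
    n_nuclei: int

    def __call__(self, x) -> np.ndarray:
        return gaussian_gradient(x, self.A, self.B, self.mu, self.sigma)

    def as_dict(self) -> dict:
        return {
            "A": self.A,
            "B": self.B,
            "mu": self.mu,
            "sigma": self.sigma,
            "residual_norm": self.residual_norm,
            "n_nuclei": self.n_nuclei,
        }


def fit_gaussian(
    x: np.ndarray,
    intensity: np.ndarray,
    sigma_bounds: tuple[float, float] = (0.005, 1.0),
    mu_bounds: tuple[float, float] = (-1.2, 1.2),
) -> GradientFit:
    """Nonlinear least-squares fit of the Gaussian gradient model.

    Deterministic initialization: mu0 at the maximum of a 15-nucleus moving
    average of intensity ordered by x, sigma0 = 0.15, B0 / A0 from the 5th and
    95th intensity percentiles.  A is bounded below by 0 and sigma to
    ``sigma_bounds``.

    Raises FitError if fewer than 8 nuclei are given or the optimizer fails.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(intensity, dtype=float)
    good = np.isfinite(x) & np.isfinite(y)
    x, y = x[good], y[good]
    if x.size < 8:
        raise FitError(f"fit failed: only {x.size} nuclei (minimum 8)")
    order = np.argsort(x)
    win = min(15, x.size)
    smoothed = (
        pd.Series(y[order]).rolling(win, center=True, min_periods=1).mean().to_numpy()
    )
    mu0 = float(np.clip(x[order][int(np.argmax(smoothed))], *mu_bounds))
    b0 = float(np.percentile(y, 5))
    a0 = max(float(np.percentile(y, 95) - b0), 1e-12)
    p0 = [a0, b0, mu0, 0.15]
    lower = [0.0, -np.inf, mu_bounds[0], sigma_bounds[0]]
    upper = [np.inf, np.inf, mu_bounds[1], sigma_bounds[1]]
    try:
        popt, _ = optimize.curve_fit(
            lambda xx, A, B, mu, sigma: gaussian_gradient(xx, A, B, mu, sigma),
            x,
            y,
            p0=p0,
            bounds=(lower, upper),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=2000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"fit failed: {exc}") from exc
    A, B, mu, sigma = (float(v) for v in popt)
    if not sigma_bounds[0] < sigma <= sigma_bounds[1]:
        raise FitError(f"fit failed: sigma {sigma:.4f} outside bounds")
    resid = y - gaussian_gradient(x, A, B, mu, sigma)
    return GradientFit(
        A=A,
        B=B,
        mu=mu,
        sigma=sigma,
        residual_norm=float(np.sqrt(np.mean(resid**2))),
        n_nuclei=int(x.size),
    )


def fit_frame(records: pd.DataFrame, intensity_col: str = "intensity") -> GradientFit:
    """Fit one frame's nucleus records (columns ``dv`` and ``intensity_col``)."""
    return fit_gaussian(records["dv"].to_numpy(), records[intensity_col].to_numpy())


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def session_factor(calib_mean: float, calib_lp: float) -> float:
    """Calib_norm = (Calib_mean / 1.74e4) * (0.1 / Calib_LP)."""
    if calib_mean <= 0 or calib_lp <= 0:
        raise ValueError("calibration mean and laser power must be positive")
    return (calib_mean / CALIB_REFERENCE_MEAN) * (CALIB_REFERENCE_LP / calib_lp)


def timecourse_factor(nuc_mean: float, nuc_lp: float) -> float:
    """timecourse_norm = nuc_mean / (100 * nuc_LP)."""
    if nuc_mean <= 0 or nuc_lp <= 0:
        raise ValueError("nuclear mean and laser power must be positive")
    return nuc_mean / (TIMECOURSE_REFERENCE * nuc_lp)


def dv_norm_curve(
    records: pd.DataFrame,
    window: int = 30,
    n_grid: int = DV_GRID_POINTS,
    nuclear_col: str = "mean_nuclear",
) -> tuple[np.ndarray, np.ndarray]:
    """DV normalization curve from nuclear intensities, on a 151-point grid.

    Per frame, nuclear intensity is ordered by folded DV coordinate |dv| and
    smoothed with a sliding window of ``window`` nuclei, then linearly
    interpolated onto the equally spaced grid on [0, 1]; curves are averaged
    over frames and rescaled to unit mean.  Frames with fewer than ``window``
    nuclei are excluded (logged).  Returns (grid, curve).
    """
    grid = np.linspace(0.0, 1.0, n_grid)
    curves = []
    for frame, group in records.groupby("frame"):
        if len(group) < window:
            log.info("frame %s excluded from curve_norm: %d nuclei", frame, len(group))
            continue
        xf = np.abs(group["dv"].to_numpy())
        order = np.argsort(xf)
        xs = xf[order]
        ys = (
            pd.Series(group[nuclear_col].to_numpy()[order])
            .rolling(window, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
        curves.append(np.interp(grid, xs, ys))
    if not curves:
        raise ValueError("no frame has enough nuclei for curve_norm")
    curve = np.mean(curves, axis=0)
    return grid, curve / curve.mean()


def apply_dv_curve(
    dv: np.ndarray, grid: np.ndarray, curve: np.ndarray
) -> np.ndarray:
    """Re-interpolate the normalization curve at folded nucleus positions."""
    return np.interp(np.abs(np.asarray(dv, dtype=float)), grid, curve)


@dataclass
class NormalizationContext:
    """Session / time-course / DV-axis normalization factors for one embryo.

    ``curve_norm`` is the 151-point DV curve on ``x_grid`` (folded axis);
    ``beta_norm`` the per-microscope-set control normalization constant.
    """

    calib_mean: float = CALIB_REFERENCE_MEAN
    calib_lp: float = CALIB_REFERENCE_LP
    nuc_mean: float = TIMECOURSE_REFERENCE
    nuc_lp: float = 1.0
    x_grid: np.ndarray = dc_field(
        default_factory=lambda: np.linspace(0.0, 1.0, DV_GRID_POINTS)
    )
    curve_norm: np.ndarray = dc_field(
        default_factory=lambda: np.ones(DV_GRID_POINTS)
    )
    beta_norm: float = 1.0

    def __post_init__(self) -> None:
        self.x_grid = np.asarray(self.x_grid, dtype=float)
        self.curve_norm = np.asarray(self.curve_norm, dtype=float)
        if len(self.curve_norm) != DV_GRID_POINTS:
            raise ValueError(f"curve_norm must have {DV_GRID_POINTS} samples")
        if self.calib_lp <= 0 or self.nuc_lp <= 0 or self.beta_norm <= 0:
            raise ValueError("normalization factors must be strictly positive")

    @property
    def calib_norm(self) -> float:
        return session_factor(self.calib_mean, self.calib_lp)

    @property
    def timecourse_norm(self) -> float:
        return timecourse_factor(self.nuc_mean, self.nuc_lp)

    def normalize(self, intensity: np.ndarray, dv: np.ndarray) -> np.ndarray:
        """raw / (Calib_norm * timecourse_norm * curve_norm(|dv|))."""
        curve = apply_dv_curve(dv, self.x_grid, self.curve_norm)
        return np.asarray(intensity, dtype=float) / (
            self.calib_norm * self.timecourse_norm * curve
        )

    def to_dict(self) -> dict:
        return {
            "calib_mean": self.calib_mean,
            "calib_lp": self.calib_lp,
            "nuc_mean": self.nuc_mean,
            "nuc_lp": self.nuc_lp,
            "x_grid": self.x_grid.tolist(),
            "curve_norm": self.curve_norm.tolist(),
            "beta_norm": self.beta_norm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationContext":
        return cls(**{**d, "x_grid": np.asarray(d["x_grid"]),
                      "curve_norm": np.asarray(d["curve_norm"])})


def normalize_fixed(
    records: pd.DataFrame,
    channels: Sequence[str] = ("mean_signal", "mean_signal2"),
    nuclear_col: str = "mean_nuclear",
    nuclear_floor: float = 0.0,
    flat_amplitude_frac: float = 1e-6,
) -> tuple[pd.DataFrame, dict[str, GradientFit]]:
    """Fixed-embryo normalization: nuclear ratio, then per-channel affine.

    Each channel is divided nucleus-wise by the nuclear-channel intensity,
    fitted to the Gaussian model over DV, and affinely normalized to
    (ratio - B) / A.  Nuclei with nuclear intensity at or below
    ``nuclear_floor`` are dropped (logged).  A channel whose fitted amplitude
    is negligible relative to its basal level (flat channel) is returned as
    ratio - B without the amplitude division, so the output stays finite.

    Returns the records with added ``ratio_<ch>`` / ``norm_<ch>`` columns and
    the per-channel fits.
    """
    out = records.copy()
    keep = out[nuclear_col].to_numpy() > nuclear_floor
    if not keep.all():
        log.info("dropping %d nuclei below the nuclear floor", (~keep).sum())
        out = out.loc[keep].copy()
    fits: dict[str, GradientFit] = {}
    dv = out["dv"].to_numpy()
    for ch in channels:
        ratio = out[ch].to_numpy() / out[nuclear_col].to_numpy()
        fit = fit_gaussian(dv, ratio)
        fits[ch] = fit
        out[f"ratio_{ch}"] = ratio
        if fit.A <= flat_amplitude_frac * max(abs(fit.B), 1.0):
            log.warning("channel %s is flat (A~0); returning ratio - B", ch)
            out[f"norm_{ch}"] = ratio - fit.B
        else:
            out[f"norm_{ch}"] = (ratio - fit.B) / fit.A
    return out, fits


# ---------------------------------------------------------------------------
# time smoothing and multi-embryo averaging
# ---------------------------------------------------------------------------


def smooth_params(fits: pd.DataFrame, window: int = 10) -> pd.DataFrame:
    """Centered moving average of per-frame fit parameters over time.

    ``fits`` must be indexed (or sortable) by ``frame`` with columns A, B,
    sigma (and optionally mu); edge frames use a shrunken window.
    """
    df = fits.sort_values("frame").set_index("frame")
    cols = [c for c in ("A", "B", "mu", "sigma") if c in df.columns]
    smoothed = df[cols].rolling(window, center=True, min_periods=1).mean()
    return smoothed.reset_index()


@dataclass
class EmbryoGradientData:
    """One live embryo's aligned, normalized input to the ensemble average.

    ``nuclei`` has columns (frame, dv, intensity) with the frame index
    already aligned across embryos (time before gastrulation); ``fits`` has
    columns (frame, A, B, mu, sigma).
    """

    nuclei: pd.DataFrame
    fits: pd.DataFrame
    name: str = ""


@dataclass
class AveragedGradient:
    """Ensemble gradient on the 36-point DV mesh, per aligned frame."""

    mesh: np.ndarray  # (36,)
    frames: np.ndarray  # (T,)
    mean: np.ndarray  # (T, 36)
    sem: np.ndarray  # (T, 36)
    interpolated: np.ndarray  # (T, 36) bool, True where the bin was empty
    params: pd.DataFrame  # frame, A, B, sigma (ensemble, smoothed)
    chi: pd.DataFrame  # embryo, frame, chi

    @property
    def dx(self) -> float:
        return float(self.mesh[1] - self.mesh[0])


def mesh_edges(n_mesh: int = MESH_POINTS) -> tuple[np.ndarray, np.ndarray]:
    """The DV mesh and its bin edges (half-width bins at 0 and 1)."""
    mesh = np.linspace(0.0, 1.0, n_mesh)
    dx = mesh[1] - mesh[0]
    edges = np.concatenate([[0.0], mesh[:-1] + dx / 2.0, [1.0]])
    return mesh, edges


def _bin_fold(x: np.ndarray, y: np.ndarray, n_mesh: int):
    """Bin folded coordinates onto the mesh; returns (mean, sem, empty)."""
    mesh, edges = mesh_edges(n_mesh)
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_mesh - 1)
    mean = np.full(n_mesh, np.nan)
    sem = np.full(n_mesh, np.nan)
    for i in range(n_mesh):
        vals = y[idx == i]
        if vals.size:
            mean[i] = vals.mean()
            sem[i] = stats.sem(vals) if vals.size > 1 else 0.0
    empty = np.isnan(mean)
    if empty.any() and not empty.all():
        good = ~empty
        mean[empty] = np.interp(mesh[empty], mesh[good], mean[good])
        sem[empty] = np.interp(mesh[empty], mesh[good], sem[good])
    return mean, sem, empty


def average_embryos(
    embryos: Sequence[EmbryoGradientData],
    n_mesh: int = MESH_POINTS,
    smooth_window: int = 10,
) -> AveragedGradient:
    """Width-rescaled, affinely pooled ensemble average of live gradients.

    See the module docstring for the procedure.  Frames are matched by their
    aligned index; embryos must share at least one frame.  Nuclei whose
    rescaled DV coordinate leaves [-1, 1] are dropped (the gradient has
    decayed to basal there).
    """
    if not embryos:
        raise AlignmentError("alignment failed: no embryos")
    frame_sets = [set(e.fits["frame"]) for e in embryos]
    common = sorted(set.intersection(*frame_sets))
    if not common:
        raise AlignmentError("alignment failed: no overlapping aligned frames")
    smoothed = [
        smooth_params(e.fits[e.fits["frame"].isin(common)], smooth_window).set_index(
            "frame"
        )
        for e in embryos
    ]
    ens = sum(s[["A", "B", "sigma"]] for s in smoothed) / len(smoothed)
    mesh, _ = mesh_edges(n_mesh)
    mean = np.full((len(common), n_mesh), np.nan)
    sem = np.full((len(common), n_mesh), np.nan)
    interp_flag = np.zeros((len(common), n_mesh), dtype=bool)
    chi_rows = []
    for ti, frame in enumerate(common):
        pooled_x = []
        pooled_y = []
        for k, e in enumerate(embryos):
            pk = smoothed[k].loc[frame]
            chi = ens.loc[frame, "sigma"] / pk["sigma"]
            chi_rows.append(
                {"embryo": e.name or k, "frame": frame, "chi": float(chi)}
            )
            nuc = e.nuclei[e.nuclei["frame"] == frame]
            x = nuc["dv"].to_numpy() * chi
            inside = np.abs(x) <= 1.0
            y = (nuc["intensity"].to_numpy()[inside] - pk["B"]) / pk["A"]
            pooled_x.append(np.abs(x[inside]))
            pooled_y.append(y)
        x = np.concatenate(pooled_x)
        y = np.concatenate(pooled_y) * ens.loc[frame, "A"] + ens.loc[frame, "B"]
        mean[ti], sem[ti], interp_flag[ti] = _bin_fold(x, y, n_mesh)
    return AveragedGradient(
        mesh=mesh,
        frames=np.asarray(common),
        mean=mean,
        sem=sem,
        interpolated=interp_flag,
        params=ens.reset_index(),
        chi=pd.DataFrame(chi_rows),
    )


# ---------------------------------------------------------------------------
# control embryos, correlation, DV time courses
# ---------------------------------------------------------------------------


def low_pass(curve: np.ndarray, window_frames: int) -> np.ndarray:
    """Centered moving average used to remove the slow control oscillation.

    A boxcar of width equal to the oscillation period nulls that frequency
    component exactly (its frequency response has a zero at 1/window).
    """
    s = pd.Series(np.asarray(curve, dtype=float))
    return s.rolling(max(int(window_frames), 1), center=True, min_periods=1).mean().to_numpy()


def control_background(
    curves: Sequence[np.ndarray],
    oscillation_period_frames: float | None = None,
) -> tuple[list[np.ndarray], float, list[np.ndarray]]:
    """Filter and set-normalize control-embryo background curves.

    ``curves`` are per-embryo DV-averaged signal intensities versus frame for
    one microscope set.  Each is low-pass filtered (boxcar of one oscillation
    period; no filtering if the period is None), beta_norm is the mean over
    all embryos and frames of the set, and every curve is divided by it.

    Returns (filtered curves, beta_norm, normalized curves).
    """
    filtered = [
        low_pass(c, round(oscillation_period_frames))
        if oscillation_period_frames
        else np.asarray(c, dtype=float)
        for c in curves
    ]
    beta = float(np.mean(np.concatenate(filtered)))
    return filtered, beta, [f / beta for f in filtered]


def dv_averaged_intensity(records: pd.DataFrame, col: str = "mean_signal") -> pd.Series:
    """Whole-DV-axis mean signal intensity per frame (control embryos)."""
    return records.groupby("frame")[col].mean()


def correlate_channels(
    embryo_records: Sequence[pd.DataFrame],
    channels: Sequence[str] = ("mean_signal", "mean_signal2"),
    min_nuclei: int = 20,
) -> tuple[list[float], float, float]:
    """Per-embryo Pearson correlation of two normalized channels.

    Each embryo's records (pooled over z) are normalized with
    :func:`normalize_fixed`; the correlation is computed across nuclei.
    Embryos with a zero-variance channel or too few nuclei are excluded
    (logged).  Returns (per-embryo rho, ensemble mean, ensemble s.d.).
    """
    rhos = []
    for k, rec in enumerate(embryo_records):
        if len(rec) < min_nuclei:
            log.warning("embryo %d excluded: only %d nuclei", k, len(rec))
            continue
        norm, _ = normalize_fixed(rec, channels=channels)
        a = norm[f"norm_{channels[0]}"].to_numpy()
        b = norm[f"norm_{channels[1]}"].to_numpy()
        if a.std() == 0 or b.std() == 0:
            log.warning("embryo %d excluded: zero-variance channel", k)
            continue
        rhos.append(float(np.corrcoef(a, b)[0, 1]))
    mean = float(np.mean(rhos)) if rhos else float("nan")
    sd = float(np.std(rhos, ddof=1)) if len(rhos) > 1 else 0.0
    return rhos, mean, sd


def time_course_at_dv(
    nuclei: pd.DataFrame,
    x0: float,
    band: float,
    intensity_col: str = "intensity",
) -> pd.DataFrame:
    """Mean normalized intensity versus frame at a fixed folded DV position.

    Nuclei with | |dv| - x0 | <= band contribute; frames with no nucleus in
    the band yield NaN (missing, not zero).
    """
    x = np.abs(nuclei["dv"].to_numpy())
    sel = np.abs(x - x0) <= band
    frames = sorted(nuclei["frame"].unique())
    rows = []
    grouped = nuclei.loc[sel].groupby("frame")[intensity_col]
    means = grouped.mean()
    sems = grouped.apply(lambda v: stats.sem(v) if len(v) > 1 else 0.0)
    for f in frames:
        rows.append(
            {
                "frame": f,
                "mean": means.get(f, np.nan),
                "sem": sems.get(f, np.nan),
                "n": int(grouped.count().get(f, 0)),
            }
        )
    return pd.DataFrame(rows)
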