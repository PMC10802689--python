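"""Mean-squared-displacement analysis and extension lengths.

Pooled MSD curves are fitted to the 2D anomalous-diffusion power law

    MSD(t) = 4*D*t^alpha

by ordinary least squares in log-log space (alpha = slope, D =
10^intercept / 4).  alpha <= 0.3 is classified as strong subdiffusion,
alpha < 1 as subdiffusive/confined, otherwise free or superdiffusive.

For confined (tethered) molecules the MSD plateaus; the square root of the
plateau value (taken at the lag nearest 1 s) is the molecule's *average
extension length*, and the maximum pairwise distance between positions in a
trajectory is its *max extension length*.  Histograms of both are
summarized by Gaussian fits.

Internal units are nm^2 and ms; diffusion coefficients are reported both as
nm^2/ms and as um^2/s (1 nm^2/ms = 1e-3 um^2/s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist
from scipy.stats import linregress

from .errors import InsufficientDataError

NM2_PER_MS_TO_UM2_PER_S = 1e-3

STRONG_SUBDIFFUSION = "strong_subdiffusion"
SUBDIFFUSIVE = "subdiffusive"
FREE = "free_superdiffusive"

STRONG_SUBDIFFUSION_ALPHA = 0.3  # published strong-subdiffusion threshold


@dataclass
class MSDCurve:
    """Pooled MSD: lag times (ms), MSD values (nm^2), per-lag pair counts."""

    lags_ms: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    n_trajectories: int


def trajectories_from_table(table: pd.DataFrame) -> tuple[list[np.ndarray], float]:
    """Split a localization table into per-trajectory (n, 2) position arrays.

    Returns ``(trajectories, frame_time_ms)`` with the frame time inferred
    from the median time step.
    """
    trajs, dts = [], []
    for _, grp in table.groupby("traj_id", sort=False):
        pos = grp[["x_nm", "y_nm"]].to_numpy(dtype=float)
        trajs.append(pos)
        t = grp["t_ms"].to_numpy(dtype=float)
        if len(t) > 1:
            dts.append(np.median(np.diff(t)))
    frame_time = float(np.median(dts)) if dts else float("nan")
    return trajs, frame_time


def _single_msd(pos: np.ndarray, max_lag: int) -> np.ndarray:
    """Time-averaged MSD of one trajectory over all frame pairs per lag."""
    n = len(pos)
    out = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        d = pos[lag:] - pos[:-lag]
        out[lag - 1] = np.mean(np.sum(d * d, axis=1))
    return out


def pooled_msd(
    trajectories: list[np.ndarray],
    frame_time: float = 50.0,
    max_lag: int | None = None,
    min_pairs: int = 4,
) -> MSDCurve:
    """Pool per-trajectory time-averaged MSDs into one weighted curve.

    Each trajectory's MSD is averaged over *all* frame pairs at each lag;
    the pooled value at a lag is the mean over trajectories weighted by
    trajectory length (frames).  Lags to which fewer than ``min_pairs``
    displacement pairs contribute in total are dropped.
    """
    trajectories = [np.asarray(p, dtype=float) for p in trajectories if len(p) >= 2]
    if not trajectories:
        raise InsufficientDataError("no trajectory with >= 2 frames")
    longest = max(len(p) for p in trajectories) - 1
    if max_lag is None:
        max_lag = longest
    max_lag = min(max_lag, longest)

    msd_sum = np.zeros(max_lag)
    w_sum = np.zeros(max_lag)
    pair_count = np.zeros(max_lag)
    for pos in trajectories:
        lmax = min(len(pos) - 1, max_lag)
        m = _single_msd(pos, lmax)
        w = float(len(pos))
        msd_sum[:lmax] += w * m
        w_sum[:lmax] += w
        pair_count[:lmax] += len(pos) - np.arange(1, lmax + 1)

    ok = (w_sum > 0) & (pair_count >= min_pairs)
    lags = (np.arange(1, max_lag + 1) * frame_time)[ok]
    if not ok.any():
        raise InsufficientDataError("no lag has enough displacement pairs")
    return MSDCurve(lags, msd_sum[ok] / w_sum[ok], pair_count[ok], len(trajectories))


@dataclass
class PowerLawFit:
    """Log-log power-law fit MSD(t) = 4*D*t^alpha of a pooled MSD curve."""

    D: float  # nm^2/ms
    alpha: float
    alpha_se: float
    intercept: float  # log10(4D)
    intercept_se: float
    label: str
    n_lags: int

    @property
    def D_um2_per_s(self) -> float:
        return self.D * NM2_PER_MS_TO_UM2_PER_S


def classify_alpha(alpha: float) -> str:
    if alpha <= STRONG_SUBDIFFUSION_ALPHA:
        return STRONG_SUBDIFFUSION
    if alpha < 1.0:
        return SUBDIFFUSIVE
    return FREE


def fit_powerlaw(curve: MSDCurve, lag_range: tuple[float, float] | None = None) -> PowerLawFit:
    """OLS fit of log10(MSD) on log10(t) over ``lag_range`` (ms).

    Zero-MSD lags are excluded (log undefined); fewer than 3 usable lags
    raises :class:`InsufficientDataError`.  alpha is the slope; D is
    10^intercept / 4 in nm^2/ms.
    """
    lags, msd = curve.lags_ms, curve.msd
    mask = msd > 0
    if lag_range is not None:
        mask &= (lags >= lag_range[0]) & (lags <= lag_range[1])
    if mask.sum() < 3:
        raise InsufficientDataError(f"need >= 3 usable lags, got {int(mask.sum())}")
    res = linregress(np.log10(lags[mask]), np.log10(msd[mask]))
    D = 10.0**res.intercept / 4.0
    return PowerLawFit(
        D=float(D),
        alpha=float(res.slope),
        alpha_se=float(res.stderr),
        intercept=float(res.intercept),
        intercept_se=float(res.intercept_stderr),
        label=classify_alpha(float(res.slope)),
        n_lags=int(mask.sum()),
    )


def max_extension(pos: np.ndarray) -> float:
    """Maximum pairwise distance between any two positions (nm)."""
    pos = np.asarray(pos, dtype=float)
    if len(pos) < 2:
        return 0.0
    return float(pdist(pos).max())


def _gauss_peak(values: np.ndarray, bins: int = 15):
    """Gaussian fit of a histogram of values; (peak, sd), sample stats fallback."""
    values = np.asarray(values, dtype=float)
    if len(values) < 5 or np.ptp(values) == 0:
        return float(np.mean(values)), float(np.std(values))
    counts, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def g(x, amp, mu, sd):
        return amp * np.exp(-((x - mu) ** 2) / (2.0 * sd**2))

    try:
        popt, _ = curve_fit(
            g, centers, counts,
            p0=[counts.max(), centers[np.argmax(counts)], np.std(values)],
            maxfev=5000,
        )
        return float(popt[1]), float(abs(popt[2]))
    except RuntimeError:
        return float(np.mean(values)), float(np.std(values))


@dataclass
class ExtensionSummary:
    """Average/max extension lengths with Gaussian histogram summaries."""

    average_extension: float  # nm, sqrt of pooled MSD at the plateau lag
    plateau_lag_used: float  # ms
    plateau_slope: float  # local log-log slope at the plateau (warning if large)
    avg_extension_per_traj: np.ndarray
    max_extension_per_traj: np.ndarray
    avg_peak: float
    avg_peak_sd: float
    max_peak: float
    max_peak_sd: float


def extension_summary(
    trajectories: list[np.ndarray],
    curve: MSDCurve,
    plateau_lag: float = 1000.0,
    frame_time: float = 50.0,
    slope_tol: float = 0.3,
) -> ExtensionSummary:
    """Extension lengths of confined molecules from the MSD plateau.

    Average extension = sqrt(MSD at the lag nearest ``plateau_lag``), with a
    warning if the local log-log slope there exceeds ``slope_tol`` (the
    curve has not plateaued).  Per-trajectory max extension = maximum
    pairwise inter-position distance.  Both per-trajectory distributions are
    summarized by Gaussian histogram fits (peak +/- SD).
    """
    if not trajectories:
        raise InsufficientDataError("no trajectories")
    lags = curve.lags_ms
    if plateau_lag < lags[0] or plateau_lag > lags[-1]:
        raise ValueError(
            f"plateau lag {plateau_lag} ms outside curve range [{lags[0]}, {lags[-1]}]"
        )
    idx = int(np.argmin(np.abs(lags - plateau_lag)))
    avg_ext = float(np.sqrt(curve.msd[idx]))

    # local log-log slope around the plateau lag
    j0, j1 = max(idx - 1, 0), min(idx + 1, len(lags) - 1)
    if j1 > j0 and curve.msd[j0] > 0 and curve.msd[j1] > 0:
        slope = float(
            (np.log10(curve.msd[j1]) - np.log10(curve.msd[j0]))
            / (np.log10(lags[j1]) - np.log10(lags[j0]))
        )
    else:
        slope = 0.0
    if slope > slope_tol:
        warnings.warn(
            f"MSD not plateaued at {lags[idx]:.0f} ms (local slope {slope:.2f})"
        )

    lag_frames = max(1, int(round(plateau_lag / frame_time)))
    per_avg = []
    for pos in trajectories:
        lf = min(lag_frames, len(pos) - 1)
        if lf >= 1:
            per_avg.append(float(np.sqrt(_single_msd(pos, lf)[lf - 1])))
    per_avg = np.asarray(per_avg)
    per_max = np.asarray([max_extension(p) for p in trajectories])

    avg_peak, avg_sd = _gauss_peak(per_avg) if len(per_avg) else (0.0, 0.0)
    max_peak, max_sd = _gauss_peak(per_max) if len(per_max) else (0.0, 0.0)
    return ExtensionSummary(
        average_extension=avg_ext,
        plateau_lag_used=float(lags[idx]),
        plateau_slope=slope,
        avg_extension_per_traj=per_avg,
        max_extension_per_traj=per_max,
        avg_peak=avg_peak,
        avg_peak_sd=avg_sd,
        max_peak=max_peak,
        max_peak_sd=max_sd,
    )
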