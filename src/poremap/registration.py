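"""Registration: nuclear-envelope localization and cloud centering.

Three steps put localizations from many pores into one frame of reference:

* :func:`locate_ne` traces the nuclear envelope in a fluorescence or
  bright-field image by fitting a 1D Gaussian to each pixel line
  perpendicular to the envelope and passing a 2nd-degree polynomial through
  the per-line peaks.
* :func:`center_localizations` centers a pooled localization cloud on the
  pore axis: the transverse (Y) histogram is fitted with a single or double
  symmetric Gaussian (model chosen by AIC) and its center shifted to zero;
  the axial (X) histogram's envelope gap is located with an inverted-Gaussian
  dip fit and shifted to zero.
* :func:`superimpose_on_centroid` translates per-pore tables so their
  reference centroids coincide at the origin, rejecting recordings whose
  drift exceeds a cutoff, and propagates the centroid's localization error
  into every merged point in quadrature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError, InsufficientDataError, NoSignalError
from .precision import combine_precision


@dataclass
class NEFit:
    """Nuclear-envelope midline: per-line Gaussian peaks + polynomial fit."""

    coeffs: np.ndarray  # highest degree first, np.polyval convention, in nm
    line_positions: np.ndarray  # coordinate along the NE (nm)
    peak_positions: np.ndarray  # fitted peak per line (nm)
    peak_errors: np.ndarray  # per-line fit SE (nm)
    precision: float  # RMS residual of the polynomial fit (nm)

    def midline(self, pos_nm):
        """Evaluate the NE midline at coordinate(s) ``pos_nm``."""
        return np.polyval(self.coeffs, pos_nm)


def _gauss(x, amp, mu, sd, base):
    return base + amp * np.exp(-((x - mu) ** 2) / (2.0 * sd**2))


def _fit_line_gaussian(profile: np.ndarray):
    """Fit a 1D Gaussian to a pixel-intensity profile; return (mu, se)."""
    x = np.arange(profile.size, dtype=float)
    base = float(profile.min())
    amp = float(profile.max() - base)
    if amp <= 0:
        raise FitError("flat profile")
    mu0 = float(np.argmax(profile))
    sd0 = max(1.0, profile.size / 10.0)
    popt, pcov = curve_fit(
        _gauss, x, profile, p0=[amp, mu0, sd0, base], maxfev=5000
    )
    if not (0 <= popt[1] <= profile.size - 1):
        raise FitError("peak outside line")
    se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.inf
    return float(popt[1]), se


def locate_ne(image: np.ndarray, pixel_size: float = 100.0, orientation: str = "columns") -> NEFit:
    """Locate the nuclear envelope midline in a 2D intensity image.

    ``orientation="columns"`` fits a Gaussian along each image column
    (profile over rows), so the midline is row-position as a function of
    column; ``"rows"`` transposes.  Lines that fail the Gaussian fit are
    skipped with a warning; fewer than 3 usable lines (or a signal-free
    image) raises :class:`NoSignalError`.  Positions are returned in nm via
    ``pixel_size``; the midline precision is the RMS residual of the
    2nd-degree polynomial through the per-line peaks.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    if orientation not in ("rows", "columns"):
        raise ValueError("orientation must be 'rows' or 'columns'")
    data = image if orientation == "columns" else image.T
    if np.ptp(data) == 0:
        raise NoSignalError("image has no intensity variation")

    lines, peaks, errors = [], [], []
    for j in range(data.shape[1]):
        profile = data[:, j]
        try:
            mu, se = _fit_line_gaussian(profile)
        except (FitError, RuntimeError) as exc:
            warnings.warn(f"locate_ne: line {j} skipped ({exc})")
            continue
        lines.append(j)
        peaks.append(mu)
        errors.append(se)
    if len(lines) < 3:
        raise NoSignalError(f"only {len(lines)} fittable lines; need >= 3")

    lines_nm = np.asarray(lines, dtype=float) * pixel_size
    peaks_nm = np.asarray(peaks) * pixel_size
    errors_nm = np.asarray(errors) * pixel_size
    coeffs = np.polyfit(lines_nm, peaks_nm, deg=2)
    resid = peaks_nm - np.polyval(coeffs, lines_nm)
    precision = float(np.sqrt(np.mean(resid**2))) if len(resid) else 0.0
    return NEFit(coeffs, lines_nm, peaks_nm, errors_nm, max(precision, 1e-12))


def _double_gauss(x, amp, c, d, sd):
    return amp * (
        np.exp(-((x - (c - d)) ** 2) / (2.0 * sd**2))
        + np.exp(-((x - (c + d)) ** 2) / (2.0 * sd**2))
    )


def _single_gauss(x, amp, mu, sd):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sd**2))


def _aic(rss: float, n: int, k: int) -> float:
    return n * np.log(max(rss, 1e-300) / n) + 2 * k


@dataclass
class CenteringReport:
    """Shifts applied by :func:`center_localizations` and their fit errors."""

    shift_x: float
    shift_y: float
    y_model: str  # "single" or "double"
    error_x: float
    error_y: float

    @property
    def total_error(self) -> float:
        return combine_precision(self.error_x, self.error_y)


def center_localizations(
    table: pd.DataFrame,
    bins: int = 30,
    fit_x_gap: bool = True,
    min_rows: int = 100,
) -> tuple[pd.DataFrame, CenteringReport]:
    """Center a pooled localization cloud on the pore axis.

    The Y histogram is fitted with a single symmetric Gaussian and with a
    double symmetric Gaussian (equal amplitudes and widths at ``c +/- d``);
    the model with lower AIC wins (ties favor the single model) and its
    center — the peak, or the midpoint of the two peaks — is shifted to 0.
    If ``fit_x_gap`` is set, the X histogram is fitted with an inverted
    Gaussian (a dip: the data gap left by the nuclear envelope) whose center
    is shifted to 0.  Fit non-convergence raises :class:`FitError` naming
    the failing dimension.
    """
    if len(table) < min_rows:
        raise InsufficientDataError(f"need >= {min_rows} rows, got {len(table)}")

    y = table["y_nm"].to_numpy()
    counts, edges = np.histogram(y, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    span = edges[-1] - edges[0]
    amp0, mu0, sd0 = float(counts.max()), float(centers[np.argmax(counts)]), span / 6.0

    half_bin = 0.5 * (edges[1] - edges[0])
    try:
        p1, c1 = curve_fit(
            _single_gauss, centers, counts, p0=[amp0, mu0, sd0],
            bounds=([0.0, edges[0], half_bin], [np.inf, edges[-1], 2.0 * span]),
            maxfev=5000,
        )
        rss1 = float(np.sum((counts - _single_gauss(centers, *p1)) ** 2))
    except RuntimeError as exc:
        raise FitError(f"Y single-Gaussian fit failed: {exc}") from exc
    # moment-based start: for a bimodal histogram the count-weighted SD
    # approximates the half-separation of the two modes
    w = counts / max(counts.sum(), 1)
    c0 = float(np.sum(w * centers))
    spread = float(np.sqrt(np.sum(w * (centers - c0) ** 2)))
    try:
        p2, c2 = curve_fit(
            _double_gauss, centers, counts,
            p0=[amp0, c0, max(spread, half_bin), max(spread / 2.0, half_bin)],
            bounds=(
                [0.0, edges[0], 0.0, half_bin],
                [np.inf, edges[-1], span, 2.0 * span],
            ),
            maxfev=5000,
        )
        rss2 = float(np.sum((counts - _double_gauss(centers, *p2)) ** 2))
        double_ok = True
    except RuntimeError:
        double_ok = False

    # double model only counts when its two peaks are actually resolved
    # (separation > one histogram bin); unresolved peaks mimic a single
    bin_width = edges[1] - edges[0]
    if double_ok and abs(p2[2]) * 2.0 < bin_width:
        double_ok = False
    if double_ok and _aic(rss2, bins, 4) < _aic(rss1, bins, 3):
        y_model, y_center = "double", float(p2[1])
        err_y = float(np.sqrt(c2[1, 1])) if np.isfinite(c2[1, 1]) else np.inf
    else:
        y_model, y_center = "single", float(p1[1])
        err_y = float(np.sqrt(c1[1, 1])) if np.isfinite(c1[1, 1]) else np.inf

    shift_x, err_x = 0.0, 0.0
    if fit_x_gap:
        x = table["x_nm"].to_numpy()
        xc_counts, x_edges = np.histogram(x, bins=bins)
        x_centers = 0.5 * (x_edges[:-1] + x_edges[1:])
        x_span = x_edges[-1] - x_edges[0]

        def dip(xv, base, amp, mu, sd):
            return base - amp * np.exp(-((xv - mu) ** 2) / (2.0 * sd**2))

        base0 = float(np.percentile(xc_counts, 80))
        # the envelope gap sits between the two data lobes: search the dip
        # only between the outermost bins that carry substantial counts
        heavy = np.nonzero(xc_counts >= 0.5 * xc_counts.max())[0]
        lo_i, hi_i = int(heavy[0]), int(heavy[-1])
        if hi_i - lo_i < 2:
            lo_i, hi_i = 0, len(xc_counts) - 1
        interior = slice(lo_i, hi_i + 1)
        mu0x = float(x_centers[interior][np.argmin(xc_counts[interior])])
        try:
            px, cx = curve_fit(
                dip, x_centers, xc_counts,
                p0=[base0, base0 - float(xc_counts[interior].min()), mu0x, x_span / 8.0],
                bounds=(
                    [0.0, 0.0, float(x_centers[lo_i]), x_span / 100.0],
                    [np.inf, np.inf, float(x_centers[hi_i]), x_span],
                ),
                maxfev=5000,
            )
        except RuntimeError as exc:
            raise FitError(f"X gap fit failed: {exc}") from exc
        shift_x = -float(px[2])
        err_x = float(np.sqrt(cx[2, 2])) if np.isfinite(cx[2, 2]) else np.inf

    shifted = table.copy()
    shifted["y_nm"] = shifted["y_nm"] - y_center
    shifted["x_nm"] = shifted["x_nm"] + shift_x
    report = CenteringReport(shift_x, -y_center, y_model, err_x, err_y)
    return shifted, report


@dataclass
class Centroid:
    """Reference centroid of one pore: position (nm) and its precision."""

    x: float
    y: float
    precision: float = 0.0


def superimpose_on_centroid(
    tables: list[pd.DataFrame],
    centroids: list[Centroid],
    drifts: list[float] | None = None,
    max_drift: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge per-pore tables into one frame centered on each pore's centroid.

    Tables whose recorded drift exceeds ``max_drift`` (nm) are rejected and
    logged.  Accepted tables are translated so their centroid sits at the
    origin; each merged row's precision becomes the quadrature sum of the
    point's own precision and the centroid's.  Trajectory ids are prefixed
    with the source index to stay unique.

    Returns ``(merged_table, log)``; raises :class:`InsufficientDataError`
    if every table is rejected.
    """
    if len(tables) != len(centroids):
        raise ValueError("one centroid per table required")
    if drifts is None:
        drifts = [0.0] * len(tables)

    rows, merged = [], []
    for i, (tab, cen, drift) in enumerate(zip(tables, centroids, drifts)):
        accepted = drift <= max_drift
        rows.append({"table": i, "drift_nm": drift, "accepted": accepted, "n_rows": len(tab)})
        if not accepted:
            continue
        t = tab.copy()
        t["x_nm"] = t["x_nm"] - cen.x
        t["y_nm"] = t["y_nm"] - cen.y
        t["precision_nm"] = combine_precision(
            t["precision_nm"].to_numpy(dtype=float), cen.precision
        )
        if len(tables) > 1:
            t["traj_id"] = [f"{i}:{tid}" for tid in t["traj_id"]]
        merged.append(t)

    log = pd.DataFrame(rows)
    if not merged:
        raise InsufficientDataError("all tables rejected by the drift filter")
    return pd.concat(merged, ignore_index=True), log
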