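"""Open/closed state statistics of axial cap ("plug") densities.

Some disordered domains alternate between an *engaged (closed)* state —
density concentrated on the transport axis — and a *disengaged (open)*
state with a hollow, ring-like density.  Scanning only a handful of pores
cannot give state percentages, so they are estimated by resampling: draw a
few hundred localizations (enough for a >= 90% reproducible
reconstruction), transform them into a radial density map, classify the map
as open or closed, and repeat thousands of times.  The fraction of closed
replicates estimates the closed-state occupancy; the central-opening radii
of open replicates are pooled and summarized by a 1- or 2-component
Gaussian mixture (the open state can show more than one opening radius).

The classifier is an explicit reconstruction (no operational definition is
standard): a map is *closed* when the mass fraction inside ``core_radius``
exceeds an occupancy threshold, defaulting to the fraction a uniform disk
would put there.  For two-state data the threshold is better calibrated
midway between the pure states' core fractions
(:func:`calibrate_occupancy_threshold`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture
from statsmodels.stats.proportion import proportion_confint

from .errors import InsufficientDataError, NoPeakError
from .transform import DensityMap, transform_2d_to_3d

OPEN = "open"
CLOSED = "closed"


@dataclass
class StateResult:
    """Classification of one density map."""

    state: str
    core_fraction: float  # mass fraction within the core radius
    opening_radius: float | None  # nm, only for open maps


def core_mass_fraction(
    dmap: DensityMap,
    core_radius: float = 10.0,
    axial_range: tuple[float, float] | None = None,
) -> float:
    """Mass fraction of the map within ``r < core_radius`` over an axial range."""
    if axial_range is None:
        x_bins = None
    else:
        lo, hi = axial_range
        x_bins = [
            b
            for b in range(len(dmap.bin_counts))
            if dmap.x_edges[b + 1] > lo and dmap.x_edges[b] < hi
        ]
        if not x_bins:
            raise InsufficientDataError("density map does not cover the axial range")
    profile = dmap.radial_profile(x_bins)
    mass = profile * dmap.annulus_areas
    total = mass.sum()
    if total <= 0:
        raise InsufficientDataError("empty map region")
    inner = mass[dmap.mid_radii < core_radius].sum()
    return float(inner / total)


def classify_state(
    dmap: DensityMap,
    axial_range: tuple[float, float] | None = None,
    core_radius: float = 10.0,
    occupancy_threshold: float | None = None,
    rise_fraction: float = 0.5,
) -> StateResult:
    """Classify a density map as open or closed.

    Closed iff the mass fraction within ``core_radius`` exceeds
    ``occupancy_threshold`` (default: the fraction expected from a uniform
    disk of the map's radial extent, ``(core_radius / r_max)^2``).  For open
    maps the opening radius is the smallest annulus mid-radius at which the
    radial density rises above ``rise_fraction`` of its maximum.
    """
    frac = core_mass_fraction(dmap, core_radius, axial_range)
    if occupancy_threshold is None:
        r_max = float(dmap.r_edges[-1])
        occupancy_threshold = (core_radius / r_max) ** 2
    if frac > occupancy_threshold:
        return StateResult(CLOSED, frac, None)
    if axial_range is None:
        profile = dmap.radial_profile()
    else:
        lo, hi = axial_range
        x_bins = [
            b
            for b in range(len(dmap.bin_counts))
            if dmap.x_edges[b + 1] > lo and dmap.x_edges[b] < hi
        ]
        profile = dmap.radial_profile(x_bins)
    peak = profile.max()
    if peak <= 0:
        raise InsufficientDataError("empty map region")
    above = np.nonzero(profile >= rise_fraction * peak)[0]
    opening = float(dmap.mid_radii[above[0]])
    return StateResult(OPEN, frac, opening)


def calibrate_occupancy_threshold(
    closed_map: DensityMap, open_map: DensityMap, core_radius: float = 10.0
) -> float:
    """Midpoint of the core mass fractions of two pure-state exemplar maps."""
    f_closed = core_mass_fraction(closed_map, core_radius)
    f_open = core_mass_fraction(open_map, core_radius)
    return 0.5 * (f_closed + f_open)


@dataclass
class StateReport:
    """Bootstrap open/closed fractions with open-state radius modes."""

    closed_fraction: float
    open_fraction: float
    closed_ci: tuple[float, float]
    open_ci: tuple[float, float]
    radius_modes: list[tuple[float, float]]  # (mode nm, weight), weights sum to 1
    iterations: int
    n_sub: int
    open_radii: np.ndarray  # per-open-iteration opening radii


def _fit_radius_modes(radii: np.ndarray, seed: int = 0) -> list[tuple[float, float]]:
    """1- or 2-component Gaussian mixture over opening radii, by BIC."""
    radii = radii[np.isfinite(radii)]
    if len(radii) == 0:
        return []
    if len(radii) < 5 or np.ptp(radii) == 0:
        return [(float(np.mean(radii)), 1.0)]
    X = radii.reshape(-1, 1)
    best, best_bic = None, np.inf
    for k in (1, 2):
        gm = GaussianMixture(n_components=k, random_state=seed).fit(X)
        bic = gm.bic(X)
        if bic < best_bic - 1e-9:
            best, best_bic = gm, bic
    modes = sorted(
        zip(best.means_.ravel().tolist(), best.weights_.ravel().tolist())
    )
    return [(float(m), float(w)) for m, w in modes]


def bootstrap_states(
    table: pd.DataFrame,
    n_sub: int = 300,
    iterations: int = 10_000,
    core_radius: float = 10.0,
    occupancy_threshold: float | None = None,
    rise_fraction: float = 0.5,
    dr: float = 10.0,
    seed: int = 0,
    sampler: str = "block",
    min_per_bin: int | None = None,
) -> StateReport:
    """Open/closed fractions by repeated subsample-transform-classify.

    Per iteration a subsample of ``n_sub`` rows is drawn without
    replacement, reconstructed at radial width ``dr`` and classified.  With
    ``sampler="block"`` (default) the subsample is a contiguous-in-time run
    of rows — state transitions happen over time, so a time window sees
    predominantly one state and the closed fraction estimates the closed-
    state time share.  ``sampler="random"`` draws rows i.i.d. instead
    (appropriate when the table holds a single state).

    Opening radii of open iterations are pooled and summarized by a 1- or
    2-component Gaussian mixture chosen by BIC.
    """
    n = len(table)
    if n_sub > n:
        raise InsufficientDataError(f"n_sub={n_sub} exceeds table rows {n}")
    if sampler not in ("block", "random"):
        raise ValueError("sampler must be 'block' or 'random'")
    if min_per_bin is None:
        min_per_bin = n_sub  # one axial bin per replicate map

    ordered = table.sort_values("t_ms", kind="stable").reset_index(drop=True)
    rng = np.random.default_rng(seed)
    n_closed = 0
    open_radii = []
    with warnings.catch_warnings():
        # per-replicate clamp diagnostics are routine at subsample scale
        warnings.simplefilter("ignore", UserWarning)
        for _ in range(iterations):
            if sampler == "block":
                start = int(rng.integers(0, n - n_sub + 1))
                sub = ordered.iloc[start : start + n_sub]
            else:
                idx = rng.choice(n, size=n_sub, replace=False)
                sub = ordered.iloc[idx]
            dmap = transform_2d_to_3d(sub, min_per_bin=min_per_bin, dr=dr)
            res = classify_state(
                dmap,
                core_radius=core_radius,
                occupancy_threshold=occupancy_threshold,
                rise_fraction=rise_fraction,
            )
            if res.state == CLOSED:
                n_closed += 1
            else:
                open_radii.append(res.opening_radius)

    closed = n_closed / iterations
    lo_c, hi_c = proportion_confint(n_closed, iterations, method="wilson")
    lo_o, hi_o = proportion_confint(iterations - n_closed, iterations, method="wilson")
    radii = np.asarray(open_radii, dtype=float)
    return StateReport(
        closed_fraction=closed,
        open_fraction=1.0 - closed,
        closed_ci=(float(lo_c), float(hi_c)),
        open_ci=(float(lo_o), float(hi_o)),
        radius_modes=_fit_radius_modes(radii, seed=seed),
        iterations=iterations,
        n_sub=n_sub,
        open_radii=radii,
    )
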