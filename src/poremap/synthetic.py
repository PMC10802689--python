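"""Synthetic inputs for every stage of the pipeline.

Three generators stand in for the study's raw microscopy data:

* :func:`sample_route_points` — localization clouds of a transport route,
  drawn on a ring of stated radius (the cylindrically symmetric geometry of
  a nucleocytoplasmic transport route projected to 2D), with optional radial
  jitter.  This is the input of the Monte Carlo reproducibility analysis.
* :func:`simulate_tethered_chain` — Brownian dynamics of a ball-and-stick
  analog of an FG-nucleoporin: beads (FG-motif regions) joined by links of
  bounded length (the intrinsically disordered regions), the root bead
  anchored to the wall of an open-ended cylindrical channel (the pore's
  central channel), with wall reflection for beads inside the channel span.
* :func:`aggregate_exposure` — camera-exposure averaging: consecutive blocks
  of fast positions are averaged into one localization per exposure, the way
  a camera integrates fast motion over a frame.

:func:`apply_localization_noise` adds Gaussian localization error of stated
SD, emulating the finite localization precision of the instrument.

All generators are deterministic under a fixed integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import TABLE_COLUMNS, validate_table


@dataclass(frozen=True)
class ChannelSpec:
    """Open-ended cylindrical channel, axis along X.

    The default geometry (40 nm length, 25 nm radius) is the analog of the
    nuclear pore complex central channel used throughout.  X is the
    nucleocytoplasmic transport axis (negative = cytoplasmic side); the
    channel spans ``|x| <= length/2``.
    """

    radius: float = 25.0  # nm
    length: float = 40.0  # nm

    def __post_init__(self):
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("channel radius and length must be positive")


@dataclass(frozen=True)
class ChainSpec:
    """Ball-and-stick tethered-polymer analog of an FG-nucleoporin.

    ``n_beads`` FG-motif beads are joined by links whose separation is capped
    at ``linker_max`` (scalar, applied to every link).  The root bead is
    anchored on the channel wall; ``anchor=None`` places each copy's root at
    a uniformly random axial position on the wall.  ``step_sd`` is the
    per-axis Gaussian displacement SD per ``base_dt`` time step; it is a user
    parameter because the study calibrates it against measured terminus
    mobility, which is data-dependent.
    """

    n_beads: int = 8
    linker_max: float = 10.0  # nm
    step_sd: float = 5.0  # nm per axis per step
    base_dt: float = 0.5  # ms
    n_copies: int = 8
    anchor: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.n_beads < 1:
            raise ValueError("n_beads must be >= 1")
        if self.linker_max < 0:
            raise ValueError("linker_max must be >= 0")
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")
        if self.step_sd < 0:
            raise ValueError("step_sd must be >= 0")
        if self.base_dt <= 0:
            raise ValueError("base_dt must be positive")

    @property
    def max_reach(self) -> float:
        """Upper bound on terminus-anchor distance: sum of link caps."""
        return (self.n_beads - 1) * self.linker_max


def _as_table(x, y, t, frame, traj_id, photons=np.nan, precision=np.nan) -> pd.DataFrame:
    table = pd.DataFrame(
        {
            "x_nm": np.asarray(x, dtype=float),
            "y_nm": np.asarray(y, dtype=float),
            "t_ms": np.asarray(t, dtype=float),
            "frame": np.asarray(frame, dtype=int),
            "traj_id": traj_id,
            "photons": photons,
            "precision_nm": precision,
        }
    )
    return table[TABLE_COLUMNS]


def sample_route_points(
    radius: float,
    radial_jitter_sd: float = 0.0,
    x_interval: tuple[float, float] = (-20.0, 20.0),
    n: int = 200,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Sample the 2D projection of points on a cylindrical transport route.

    Each point: axial ``x ~ Uniform(x_interval)``, angle ``theta ~
    Uniform(0, 2*pi)``, radius ``r ~ Normal(radius, radial_jitter_sd)``
    truncated at 0 (negative draws clipped).  The recorded observable is the
    projection ``(x, y = r*cos(theta))`` — the microscope sees X and Y only.

    Parameters are in nm.  Returns a localization table whose rows are one
    trajectory each (independent localizations, 50 ms apart by convention).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radial_jitter_sd < 0:
        raise ValueError("radial_jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    x = rng.uniform(x_interval[0], x_interval[1], size=n)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    if radial_jitter_sd > 0:
        r = np.clip(rng.normal(radius, radial_jitter_sd, size=n), 0.0, None)
    else:
        r = np.full(n, float(radius))
    y = r * np.cos(theta)
    frame = np.arange(n)
    return _as_table(x, y, t=frame * 50.0, frame=frame, traj_id=[f"pt{i}" for i in range(n)])


def sample_cylinder_volume(
    radius: float,
    x_interval: tuple[float, float] = (-20.0, 20.0),
    n: int = 200,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Sample points uniform in the *volume* of a cylinder, projected to 2D.

    Companion sampler to :func:`sample_route_points` for oracle tests: a
    uniform-volume cylinder projects to a flat per-area radial density, so
    the 2D-to-3D inversion of these points must be flat across annuli.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(seed)
    x = rng.uniform(x_interval[0], x_interval[1], size=n)
    # uniform in the disk: r ~ R*sqrt(U)
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    y = r * np.cos(theta)
    frame = np.arange(n)
    return _as_table(x, y, t=frame * 50.0, frame=frame, traj_id=[f"pt{i}" for i in range(n)])


def simulate_tethered_chain(
    chain: ChainSpec,
    channel: ChannelSpec,
    burn_in: float = 10_000.0,
    record: float = 10_000.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Brownian dynamics of tethered bead-chains in a cylindrical channel.

    Per time step and per chain copy, every non-root bead takes an isotropic
    Gaussian step (per-axis SD ``chain.step_sd``); then constraints are
    enforced in fixed order: (1) each link is clipped to ``linker_max`` by
    projecting the outer bead toward its inner neighbour, from the root
    outward; (2) beads whose axial coordinate lies inside the channel span
    are reflected off the cylinder wall (radial coordinate ``r -> 2*R - r``);
    the root bead stays at its anchor.  The first ``burn_in`` ms are
    discarded to erase the initial condition; terminus positions are then
    recorded every ``base_dt`` for ``record`` ms.

    Returns an array of shape ``(n_copies, n_frames, 3)`` of terminus
    positions (x, y, z) in nm.  ``n_frames = round(record / base_dt)``.
    """
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    if record <= 0:
        raise ValueError("record must be positive")
    rng = np.random.default_rng(seed)
    n_copies, n_beads = chain.n_copies, chain.n_beads
    half_len = channel.length / 2.0

    # anchors on the channel wall
    if chain.anchor is not None:
        anchors = np.tile(np.asarray(chain.anchor, dtype=float), (n_copies, 1))
    else:
        ax = rng.uniform(-half_len, half_len, size=n_copies)
        phi = rng.uniform(0.0, 2.0 * np.pi, size=n_copies)
        anchors = np.column_stack(
            [ax, channel.radius * np.cos(phi), channel.radius * np.sin(phi)]
        )

    # start all beads collapsed onto the anchor; burn-in relaxes the chain
    pos = np.repeat(anchors[:, None, :], n_beads, axis=1)  # (copies, beads, 3)

    n_burn = int(round(burn_in / chain.base_dt))
    n_rec = int(round(record / chain.base_dt))
    out = np.empty((n_copies, n_rec, 3))

    for step in range(n_burn + n_rec):
        if n_beads > 1 and chain.step_sd > 0:
            pos[:, 1:, :] += rng.normal(0.0, chain.step_sd, size=(n_copies, n_beads - 1, 3))
        # link clipping, root outward
        for b in range(1, n_beads):
            d = pos[:, b, :] - pos[:, b - 1, :]
            dist = np.linalg.norm(d, axis=1)
            over = dist > chain.linker_max
            if over.any():
                if chain.linker_max == 0:
                    pos[over, b, :] = pos[over, b - 1, :]
                else:
                    scale = (chain.linker_max / dist[over])[:, None]
                    pos[over, b, :] = pos[over, b - 1, :] + d[over] * scale
        # wall reflection for beads axially inside the channel
        inside = np.abs(pos[:, :, 0]) <= half_len
        rad = np.hypot(pos[:, :, 1], pos[:, :, 2])
        breach = inside & (rad > channel.radius)
        if breach.any():
            r_old = rad[breach]
            r_new = np.clip(2.0 * channel.radius - r_old, 0.0, None)
            scale = r_new / r_old
            pos[:, :, 1][breach] *= scale
            pos[:, :, 2][breach] *= scale
        pos[:, 0, :] = anchors  # root fixed
        if step >= n_burn:
            out[:, step - n_burn, :] = pos[:, -1, :]
    return out


def aggregate_exposure(
    series: np.ndarray,
    k: int,
    base_dt: float = 0.5,
    traj_id: str = "sim",
) -> pd.DataFrame:
    """Average consecutive blocks of ``k`` positions into camera localizations.

    Mimics camera integration: a series sampled at ``base_dt`` becomes one
    localization per ``k*base_dt`` exposure (k=100 maps a 0.5 ms series to
    50 ms localizations).  Blocks are non-overlapping; a trailing partial
    block is dropped (an incomplete camera frame is discarded).  The output
    time stamp is the block midpoint.  3D input is projected to (x, y).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[1] not in (2, 3):
        raise ValueError("series must be (n, 2) or (n, 3)")
    if k < 1:
        raise ValueError("k must be >= 1")
    n = series.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds series length {n}")
    n_blocks = n // k
    blocks = series[: n_blocks * k].reshape(n_blocks, k, series.shape[1])
    mean = blocks.mean(axis=1)
    t_mid = (np.arange(n_blocks) * k + (k - 1) / 2.0) * base_dt
    frame = np.arange(n_blocks)
    return _as_table(mean[:, 0], mean[:, 1], t=t_mid, frame=frame, traj_id=traj_id)


def aggregate_exposure_copies(
    series: np.ndarray, k: int, base_dt: float = 0.5
) -> pd.DataFrame:
    """Apply :func:`aggregate_exposure` per chain copy and concatenate.

    ``series`` has shape ``(n_copies, n_frames, 3)`` as returned by
    :func:`simulate_tethered_chain`; each copy becomes one trajectory.
    """
    tables = [
        aggregate_exposure(series[c], k, base_dt=base_dt, traj_id=f"copy{c}")
        for c in range(series.shape[0])
    ]
    return pd.concat(tables, ignore_index=True)


def sample_ring_walk(
    radius: float,
    angular_step_sd: float,
    n_steps: int,
    base_dt: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Angular Brownian walk on a transverse ring of fixed radius.

    The ring lies in the (y, z) plane — transverse to the transport axis —
    so the walk emulates a terminus diffusing on a cylindrical shell at one
    axial position.  Returns an ``(n_steps, 3)`` series
    ``(0, radius*sin(theta_t), radius*cos(theta_t))`` with ``theta`` a
    Gaussian random walk of per-step SD ``angular_step_sd`` (radians).  Used
    to demonstrate that exposure averaging biases the apparent radius of
    shell-confined motion inward: the mean of points on an arc lies inside
    the ring.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    theta = np.cumsum(rng.normal(0.0, angular_step_sd, size=n_steps))
    return np.column_stack(
        [np.zeros(n_steps), radius * np.sin(theta), radius * np.cos(theta)]
    )


def simulate_disk_diffusion(
    radius: float,
    step_sd: float,
    n_steps: int,
    n_trajectories: int = 1,
    seed: int | np.random.Generator = 0,
) -> list[np.ndarray]:
    """2D Brownian motion confined to a reflecting disk of given radius.

    Per step each particle takes an isotropic Gaussian step (per-axis SD
    ``step_sd``); excursions beyond the disk are reflected radially
    (``r -> 2*radius - r``).  At stationarity positions are uniform in the
    disk, so the MSD plateaus at ``E|dX|^2 = radius^2`` — the closed-form
    limit used to validate extension lengths.  Returns one ``(n_steps, 2)``
    array per trajectory.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if step_sd < 0:
        raise ValueError("step_sd must be >= 0")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_trajectories):
        pos = np.zeros(2)
        traj = np.empty((n_steps, 2))
        for t in range(n_steps):
            pos = pos + rng.normal(0.0, step_sd, 2)
            r = np.hypot(pos[0], pos[1])
            if r > radius:
                pos = pos * (max(2.0 * radius - r, 0.0) / r)
            traj[t] = pos
        out.append(traj)
    return out


def apply_localization_noise(
    table: pd.DataFrame,
    sigma: float | np.ndarray,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Add Gaussian localization error of SD ``sigma`` (nm) to x and y.

    ``sigma`` may be a scalar or a per-row array (e.g. from the localization
    precision formula).  The precision column of the output is set to the
    applied sigma.  ``sigma=0`` returns an identical table.
    """
    sigma_arr = np.broadcast_to(np.asarray(sigma, dtype=float), (len(table),))
    if (sigma_arr < 0).any():
        raise ValueError("sigma must be >= 0")
    out = table.copy()
    if len(table) and np.any(sigma_arr > 0):
        rng = np.random.default_rng(seed)
        out["x_nm"] = out["x_nm"].to_numpy() + rng.normal(0.0, 1.0, len(out)) * sigma_arr
        out["y_nm"] = out["y_nm"].to_numpy() + rng.normal(0.0, 1.0, len(out)) * sigma_arr
    out["precision_nm"] = np.where(sigma_arr > 0, sigma_arr, table["precision_nm"])
    return out
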