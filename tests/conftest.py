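"""Shared fixtures: programmatic synthetic tables used across the suite."""

import numpy as np
import pandas as pd
import pytest

from poremap import sample_route_points


def make_table(x, y, frame_time=50.0, traj_id=None, precision=np.nan, photons=np.nan):
    """Assemble a canonical localization table from coordinate arrays."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if traj_id is None:
        traj_id = [f"p{i}" for i in range(n)]
    return pd.DataFrame(
        {
            "x_nm": x,
            "y_nm": y,
            "t_ms": np.arange(n) * frame_time,
            "frame": np.arange(n),
            "traj_id": traj_id,
            "photons": photons,
            "precision_nm": precision,
        }
    )


def single_trajectory(positions, frame_time=50.0, traj_id="t0", precision=np.nan):
    """One trajectory from an (n, 2) position array."""
    pos = np.asarray(positions, dtype=float)
    return make_table(
        pos[:, 0], pos[:, 1], frame_time=frame_time,
        traj_id=[traj_id] * len(pos), precision=precision,
    )


def planted_state_table(frac_closed, n_blocks=10, block=1000, seed=0,
                        open_radius=30.0, closed_sd=6.0):
    """Epoch-structured mixture of closed (central blob) and open (ring) states.

    Time is divided into ``n_blocks`` equal blocks; a fraction
    ``frac_closed`` of them hold closed-state localizations (Gaussian blob
    of SD ``closed_sd`` on the axis), the rest open-state localizations
    (ring of radius ``open_radius`` with slight radial jitter).  Returns
    ``(table, labels)`` with per-block ground-truth labels (1 = closed).
    """
    rng = np.random.default_rng(seed)
    n_closed = int(round(frac_closed * n_blocks))
    labels = np.array([1] * n_closed + [0] * (n_blocks - n_closed))
    rng.shuffle(labels)
    rows = []
    t0 = 0
    for lb in labels:
        if lb:
            x = rng.uniform(-20, 20, block)
            y = rng.normal(0, closed_sd, block)
        else:
            tab = sample_route_points(open_radius, 2.0, (-20, 20), block, seed=rng)
            x, y = tab["x_nm"].to_numpy(), tab["y_nm"].to_numpy()
        rows.append(
            pd.DataFrame(
                {
                    "x_nm": x,
                    "y_nm": y,
                    "t_ms": np.arange(t0, t0 + block) * 50.0,
                    "frame": np.arange(block),
                    "traj_id": [f"b{t0 + i}" for i in range(block)],
                    "photons": np.nan,
                    "precision_nm": np.nan,
                }
            )
        )
        t0 += block
    return pd.concat(rows, ignore_index=True), labels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
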