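"""Spatial overlap of two density maps with axial-first gating.

Reconstructs two routes whose axial densities peak at different positions
along the transport axis but overlap substantially, then reports
Pearson/Spearman correlations: radial overlap is only evaluated when the
axial profiles already correlate positively.
"""

import numpy as np
import pandas as pd

from poremap import dimension_correlation, transform_2d_to_3d


def route_map(radius, x_center, x_sd, seed, n=4000):
    """Route with a Gaussian axial density centered at ``x_center``."""
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi, n)
    r = rng.normal(radius, 2.0, n)
    tab = pd.DataFrame({
        "x_nm": rng.normal(x_center, x_sd, n), "y_nm": r * np.cos(theta),
        "t_ms": np.arange(n) * 50.0, "frame": np.arange(n),
        "traj_id": [f"p{i}" for i in range(n)],
        "photons": np.nan, "precision_nm": np.nan,
    })
    return transform_2d_to_3d(tab, min_per_bin=500, dr=10.0)


a = route_map(25.0, x_center=-10.0, x_sd=25.0, seed=10)
b = route_map(25.0, x_center=5.0, x_sd=25.0, seed=11)
rep = dimension_correlation(a, b)

print(f"axial overlap region: {rep.x_overlap[0]:.0f} to {rep.x_overlap[1]:.0f} nm")
print(f"X: Pearson {rep.pearson_x:+.3f}, Spearman {rep.spearman_x:+.3f}")
if rep.r_evaluated:
    print(f"R: Pearson {rep.pearson_r:+.3f}, Spearman {rep.spearman_r:+.3f}")
else:
    print(f"R: not evaluated ({rep.gate_reason})")
# Axial densities peaking 15 nm apart still correlate positively, opening
# the gate; the shared 25 nm shell then gives a strongly positive radial
# correlation.
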