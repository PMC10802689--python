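"""Reconstruct the 3D radial density of a transport route from 2D data.

Samples the microscope's-eye 2D projection of a cylindrically symmetric
route of 25 nm radius, adds 10 nm localization noise, and inverts the
transverse histograms into per-annulus densities ("onion peeling").
"""

import numpy as np

from poremap import (
    apply_localization_noise,
    fit_radial_peak,
    sample_route_points,
    select_r_binwidth,
    transform_2d_to_3d,
)

clean = sample_route_points(radius=25.0, radial_jitter_sd=0.0,
                            x_interval=(-20.0, 20.0), n=2000, seed=3)
noisy = apply_localization_noise(clean, sigma=10.0, seed=4)

choice = select_r_binwidth(noisy, candidates=[5.0, 10.0, 15.0], min_per_bin=2000)
print("bin-width report:")
print(choice.table.round(3).to_string(index=False))
print(f"chosen radial bin width: {choice.chosen} nm")

dmap = transform_2d_to_3d(noisy, min_per_bin=200, dr=choice.chosen)
print(f"\n{len(dmap.bin_counts)} axial bins x {dmap.rho.shape[1]} radial bins")
for b in range(len(dmap.bin_counts)):
    peak = fit_radial_peak(dmap, b)
    print(f"  axial bin {b} [{dmap.x_edges[b]:6.1f}, {dmap.x_edges[b+1]:6.1f}) nm: "
          f"peak {peak.radius:5.1f} +/- {peak.se:4.1f} nm "
          f"({dmap.bin_counts[b]} localizations)")
# Most axial bins recover the 25 nm route radius to within a few nm at
# 200 localizations per bin despite the 10 nm localization noise; bins
# with a large quoted error flag unstable fits at this sample size.
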