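# poremap

Single-molecule analysis of intrinsically disordered FG-nucleoporins in
live nuclear pore complexes (NPCs).

High-speed single-molecule tracking of one pore at a time yields 2D
localization tables of fluorophore-tagged nucleoporin termini. `poremap`
turns those tables into quantitative statements about where the disordered
FG domains live and how they move:

- **Filtering** — the localization-precision formula for moving emitters,
  and residence-time / precision / trajectory-length filters that isolate
  anchored molecules from free dye and unbound labeled protein.
- **Registration** — nuclear-envelope localization in images (per-line
  Gaussian fits + 2nd-degree polynomial), centering of pooled clouds on the
  pore axis, and superimposition of many pores onto a common centroid with
  quadrature error propagation.
- **MSD analysis** — pooled, length-weighted mean-squared-displacement
  curves fitted to the 2D anomalous-diffusion power law `MSD(t) = 4Dt^α`
  in log-log space, with α ≤ 0.3 flagged as strong subdiffusion, plus
  average extension (√MSD at the plateau, typically t = 1 s) and max
  extension (largest pairwise excursion) lengths.
- **2D→3D transformation** — the core algorithm: under the NPC's
  cylindrical symmetry, the transverse |y| histogram of an axial bin is an
  upper-triangular linear mixture of annulus densities,
  `h_j = Σ_{i≥j} ρ_i A_ji`, solved exactly by back-substitution ("onion
  peeling"). The annulus-strip area matrix `A` is closed-form, so forward
  projection followed by inversion is the identity to machine precision.
- **Monte Carlo reproducibility** — route localization precision (SD of
  fitted radial peaks over repeated simulated datasets) and the
  reproducibility rate as a function of sample size, localization
  precision, and route radius; the basis of the ≥ 200 localizations per
  axial bin rule.
- **State statistics** — bootstrap open/closed ("plug") state percentages
  by repeated subsample → transform → classify, with open-state opening
  radii summarized by a Gaussian mixture.
- **Overlap statistics** — Pearson/Spearman correlation of two maps'
  marginal profiles, with radial overlap evaluated only when axial overlap
  is present.
- **Synthetic data** — every input the pipeline needs can be generated:
  ring-route clouds, a tethered bead-chain (ball-and-stick) Brownian
  simulator in a cylindrical channel, camera-exposure averaging, and
  Gaussian localization noise. All generators are seed-deterministic.

## Worked example

```python
from poremap import (sample_route_points, apply_localization_noise,
                     transform_2d_to_3d, fit_radial_peak)

clean = sample_route_points(radius=25.0, radial_jitter_sd=0.0,
                            x_interval=(-20.0, 20.0), n=2000, seed=3)
noisy = apply_localization_noise(clean, sigma=10.0, seed=4)
dmap = transform_2d_to_3d(noisy, min_per_bin=2000, dr=10.0)
peak = fit_radial_peak(dmap, 0)
print(f"fitted route radius: {peak.radius:.1f} +/- {peak.se:.1f} nm")
```

```
fitted route radius: 21.7 +/- 1.1 nm
```

2,000 projected localizations of a 25 nm-radius route, blurred by 10 nm
localization error, reconstruct to a radial peak within one 10 nm radial
bin of the truth. The `examples/` directory holds one short narrative
script per capability (filtering, extension lengths, transformation,
reproducibility, state bootstrap, overlap); each prints the numbers it
computes and says what they mean. A thin CLI mirrors the stages
(`poremap simulate | noise | filter | locate-ne | center | superimpose |
msd | transform | repro | states | overlap | run`).

## Documentation

`docs/methods.md` describes the models, their assumptions, the numerical
choices (constraint ordering in the simulator, clamping of negative
densities, weighted peak fitting), what the synthetic generators do and do
not emulate, and known limitations.
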