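"""Analyze a coarse-grained bilayer trajectory for scrambling and disruption.

Builds a synthetic Martini-like bilayer (one phosphate bead per lipid) with
five planted flip-flop events, a thinned membrane patch and a hydrated
defect disc, writes it as GRO text, reads it back, and runs the three
analyzers: scrambled-lipid time series, membrane-thickness map, and
water-defect map.
"""

import numpy as np

import scramkit as sk

spec = sk.TrajectorySpec(
    n_lipids=100,
    n_waters=200,
    box=(10.0, 10.0, 10.0),
    n_frames=120,
    frame_interval_ps=10_000.0,  # one frame every 10 ns
    planted_flips=((3, 20), (17, 40), (42, 60), (55, 80), (90, 100)),
    thinned_region=sk.DiscRegion(cx=5.0, cy=5.0, radius=1.5, phosphate_offset_nm=1.05),
    defect_region=sk.DiscRegion(cx=5.0, cy=5.0, radius=1.0, waters_per_frame=10),
    seed=7,
)
frames = sk.generate_trajectory(spec)

series = sk.scrambled_series(frames, sample_every_ns=10.0, window_ns=200.0)
print(f"scrambled lipids at the end: {series.percent[-1]:.1f}% "
      f"({int(series.percent[-1])} of {spec.n_lipids} lipids changed leaflet)")
print(f"scrambling rate (slope of % vs time): {series.rate_percent_per_us:.2f} %/us")

thick = sk.thickness_map(frames, sample_every_ps=10_000.0, min_samples=100)
inside = np.zeros_like(thick.values, dtype=bool)
xc = (thick.x_edges[:-1] + thick.x_edges[1:]) / 2
yc = (thick.y_edges[:-1] + thick.y_edges[1:]) / 2
xx, yy = np.meshgrid(xc, yc, indexing="ij")
inside = (xx - 5.0) ** 2 + (yy - 5.0) ** 2 <= 1.5**2
print(f"thickness far from the patch: {np.nanmean(thick.values[~inside]):.2f} nm")
print(f"thickness inside the thinned patch: {np.nanmean(thick.values[inside]):.2f} nm "
      "(the kind of local thinning a scramblase interface produces)")

defect = sk.water_defect_map(frames, sample_every_ps=10_000.0, min_samples=100)
print(f"water-defect beads per frame within 1 nm of the core: {np.nansum(defect.values):.1f} "
      f"(all inside the planted disc; {int(defect.mask.sum())} of {defect.mask.size} bins masked "
      "by the <100-sample rule)")
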