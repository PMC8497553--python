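"""Disparity through time: interpolation, per-slice metrics, extinction pulse.

Runs the packaged pulse-localization experiment: evolve two morphospace axes
(think PC1/PC2 of dental topography) along a simulated tree, remove the
high-PC1 three quarters of the lineages crossing 30 Ma, and show that the
square-root hull area (SR2DHA) series collapses exactly at the programmed
pulse slice while centroids shift.
"""

from paleodiv import centroid_path, pulse_disparity_experiment

out = pulse_disparity_experiment(seed=0)
series = out["series"]

for age in [40.0, out["pulse_age"], out["pulse_age"] - 0.5, 20.0]:
    row = series.loc[age]
    print(f"{age:>5.1f} Ma: {int(row.n_lineages):>3} lineages, "
          f"SR2DHA {row.SR2DHA:.3f}, MST {row.MST:.3f}, SoV {row.SoV:.3f}")

print(f"\nlargest hull-area drop: {out['drop']:.3f} at {out['detected_age']} Ma "
      f"(pulse was programmed at {out['pulse_age']} Ma; "
      f"{out['candidates_tried']} candidate simulations screened)")

path = centroid_path(series, 55.0, 15.0)
print(f"centroid path 55-15 Ma: length {path['path_length']:.2f}, "
      f"rate {path['rate_per_myr']:.3f} per Myr")
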