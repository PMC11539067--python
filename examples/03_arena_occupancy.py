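"""Station-holding in a current: centre occupancy and heat maps.

Simulates a wildtype fish (mean-reverting pull toward the centre line of
the flow channel) and a mutant (no pull, larger dispersal), then
quantifies the difference the way the behavioural assay does: fraction
of time in the central band and a position heat map normalised to 100%.
"""

from finwave.features import centre_occupancy, occupancy_map
from finwave.synthetic import ArenaSpec, simulate_arena_track

spec = ArenaSpec(stream_speed_label="medium")
print(f"arena {spec.width_mm:.0f} x {spec.height_mm:.0f} mm, "
      f"'{spec.stream_speed_label}' stream ({spec.flow_ml_s:.0f} ml/s), "
      f"centre band = {spec.centre_band_frac:.2f} of channel width")

for preset in ("wildtype", "mutant"):
    traj, truth = simulate_arena_track(spec, preset, duration_s=30.0,
                                       fps=50.0, seed=3)
    occ = centre_occupancy(traj, spec)
    om = occupancy_map(traj, spec, n_bins=12)
    print(f"  {preset:9s} centre occupancy = {occ:.2f}, "
          f"heat-map total = {om.percent.sum():.1f}%, "
          f"hottest bin = {om.percent.max():.1f}%")

print("\nThe wildtype holds the centre of the current (high centre "
      "occupancy, concentrated heat map); the mutant disperses across "
      "the channel — the construction the real assay is designed to detect.")
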