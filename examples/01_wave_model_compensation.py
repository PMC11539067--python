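"""Can a bigger, caudally shifted pectoral standing wave rescue a
stiffened tail?

Builds the three bending-wave conditions (fully flexible, caudally
stiffened, stiffened + compensating standing wave), converts each into
midline kinematics, and balances elongated-body thrust against drag to
get a steady swimming speed.
"""

import numpy as np

from finwave.propulsion import (
    PRESETS,
    PropulsionConfig,
    compensation_grid_search,
    steady_speed,
    tail_kinematics,
)
from finwave.wave_model import generate_bending_field, midlines_from_bending

cfg = PropulsionConfig()
print("Steady swimming speed per condition (body lengths per second):")
for name, params in PRESETS.items():
    field = generate_bending_field(params, duration_s=2.0, fps=200.0)
    seq = midlines_from_bending(field, params)
    res = steady_speed(tail_kinematics(seq), cfg, label=name)
    print(f"  {name:12s} {res.steady_speed_bl_s:6.3f} BL/s")

grid = compensation_grid_search(cfg=cfg)
best = grid.iloc[0]
within = grid[grid.rel_gap <= 0.05]
print("\nGrid search over standing-wave (amplitude, peak position):")
print(f"  fastest pair: amp={best.standing_amp_rad:.3f} rad, "
      f"peak={best.standing_peak_pos:.2f} BL")
print(f"  pairs within 5% of the flexible speed: {len(within)}")
print(f"  their peak positions: "
      f"{[float(v) for v in sorted(within.standing_peak_pos.round(2).unique())]}")
print("\nThe stiff condition is slowest; an enlarged standing wave restores "
      "speed, and the fastest compensating pair places its peak caudal to "
      "the wildtype position (0.25 BL) — the model's core prediction.")
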