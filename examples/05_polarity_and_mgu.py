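"""Cortical actin polarity and male-germ-unit translocation timing.

Renders one tube with actin and sperm-membrane channels: F-actin is
polarized opposite the germination site before emergence, and the sperm
membrane extension exits the grain when the tube reaches ~350 um^2.
"""

import numpy as np

from pollengerm.cohorts import kinetics_cohort
from pollengerm.pipeline import analyze_tube

tl, gt = next(
    kinetics_cohort(
        n_tubes=1, seed=11, event=("mgu", 350.0),
        channels=("cytoplasm", "actin", "sperm_membrane"),
    )
)
a = analyze_tube(tl, "demo")

p = a.polarity
print(f"actin polarity index: {p.polarity_index:.2f} "
      "(0 = uniform cortical ring, 1 = fully focused)")
print(f"polarity direction vs germination site: "
      f"{np.rad2deg(p.angle_to_germination):.0f} deg "
      "(the cortical F-actin cap sits opposite the future tube)")

print(f"\nscheduled translocation: frame {gt.mgu_frame} "
      f"(true area {gt.mgu_area_um2:.1f} um^2)")
print(f"detected translocation:  frame {a.mgu.frame} at t = {a.mgu.time_min:.0f} min, "
      f"measured area {a.mgu.area_at_translocation:.1f} um^2")
print("the sperm cells enter the tube only after rapid tip growth is "
      "established, at a reproducible tube size")
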