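"""Pre-germination vesicle peaks: 'two knocks on the door'.

Simulates 10 grains, 8 of them with one or two high-intensity vesicle-marker
peaks injected near the future germination site between 20 and 3 min before
emergence, runs peak detection on the 0.5% stack-histogram ROIs, and prints
the population frequency table.
"""

import numpy as np

from pollengerm.cohorts import vesicle_peak_cohort
from pollengerm.pipeline import analyze_tube
from pollengerm.polarization import population_peak_stats

events_per_tube = []
for i, (tl, gt) in enumerate(vesicle_peak_cohort(n_tubes=10, n_concordant=8, seed=3)):
    a = analyze_tube(tl, f"grain{i:02d}")
    events_per_tube.append(a.peak_events)
    pre = [e for e in a.peak_events if e.time_min < 0]
    desc = ", ".join(
        f"{e.time_min:+.0f} min @ {np.rad2deg(e.direction):+.0f} deg"
        f"{' (concordant)' if e.site_concordant else ''}"
        for e in pre
    ) or "none"
    print(f"grain{i:02d} [{gt.scenario:>10s}] detected peaks: {desc}")

stats = population_peak_stats(events_per_tube)
print(f"\ngrains with >=1 site-concordant pre-germination peak: "
      f"{stats['concordant_pre_germination']}/{stats['n_tubes']}")
print(f"peaks per reporting window {stats['bins_min']}: {stats['bin_counts']}")
print(f"one peak: {stats['one_peak']}; two or more: {stats['two_or_more_peaks']}")
print("transient vesicle accumulation marks the future growth site before "
      "the tube emerges")
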