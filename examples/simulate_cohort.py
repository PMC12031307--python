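"""Generate a synthetic storage cohort and summarize its structure.

Draws the full default design (2 sizes x 2 storage temperatures x 46
fruit, measured on days 0/1/2), then prints the group counts and the
spectral drift each storage group exhibits at low frequency.
"""

import numpy as np

from bisfruit import FrequencyGrid, StudyDesign, generate_cohort

design = StudyDesign(seed=7)
records, spectra = generate_cohort(design)

print(f"fruit: {len(records)}   spectra: {len(spectra)}")
for size in ("small", "large"):
    diams = [r.diameter_mm for r in records if r.size == size]
    print(f"  {size:>5}: n={len(diams)}  diameter {np.mean(diams):.1f} "
          f"+/- {np.std(diams):.1f} mm")

grid = FrequencyGrid.default()
by = {(s.metadata.sample_id, s.metadata.day): s for s in spectra}
print("\nlow-frequency drift (|Z| at 50 Hz, group means):")
for storage in ("room", "cold"):
    group = [r for r in records if r.storage == storage]
    for day in (0, 1, 2):
        z = np.mean([by[(r.sample_id, day)].magnitude[0] for r in group])
        print(f"  {storage:>4} day {day}: {z:9.0f} Ohm")
print(
    "\nRoom-stored fruit lose water, so their resistances (and hence the\n"
    "low-frequency impedance) climb day by day; cold-stored fruit stay\n"
    "within measurement noise of their day-0 state."
)
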