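"""Count nuclei on simulated fields and apply the Low Cell Count gate.

Simulates wells at a range of seeding densities around the screen's median
(187.5 cells/field, 30 fields/well), detects and gates nuclei per field, and
bins each well at the 3,300-nuclei threshold.
"""

from pathlib import Path

import pandas as pd

from woundscreen.nuclei import bin_cell_count, count_valid_nuclei, detect_nuclei, well_total
from woundscreen.synthetic import ImageSpec, generate_nuclei_image

RESULTS = Path(__file__).resolve().parents[1] / "results"
N_FIELDS = 6          # fields simulated per well (scaled up to the 30-field total)

rows = []
for well_idx, per_field in enumerate([187, 150, 110, 80, 40]):
    counts = []
    for f in range(N_FIELDS):
        spec = ImageSpec(768, 768, pixel_size_um=1.0, noise_sd=25.0,
                         seed=1000 * well_idx + f)
        img, truth = generate_nuclei_image(spec, per_field)
        counts.append(count_valid_nuclei(detect_nuclei(img)))
    total = well_total(counts, scale_to_full=True)
    rows.append({"well": f"W{well_idx + 1}", "true_per_field": per_field,
                 "mean_detected_per_field": sum(counts) / len(counts),
                 "scaled_total": total, "bin": bin_cell_count(total)})

df = pd.DataFrame(rows)
RESULTS.mkdir(exist_ok=True)
df.to_csv(RESULTS / "nuclei_counts.csv", index=False)
print(df.to_string(index=False))
print("\nwells below 110 cells/field (total < 3,300) are binned LowCellCount;"
      "\nthat bin later suppresses any migration call for the well.")
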