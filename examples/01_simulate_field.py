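"""Generate a synthetic 3-acre field trial and inspect its structure.

The generator emulates a 3 acres x 10 zones x 3 plants tomato trial:
each zone carries one condition (Healthy / Mild / Severe), and each
plant's six perceptual trait intensities are the condition means plus
severity-scaled Gaussian noise.
"""

import numpy as np

from pgk import generate_field, write_trait_table
from pgk.encoding import TRAIT_CODES

records = generate_field(seed=42)
print(f"{len(records)} plants across "
      f"{len({(r.acre_id, r.zone_id) for r in records})} zones")

labels = [r.condition for r in records]
print("class counts:", {c: labels.count(c) for c in sorted(set(labels))})

for cond in ("Healthy", "Mild", "Severe"):
    mat = np.array(
        [[r.values[c] for c in TRAIT_CODES] for r in records if r.condition == cond]
    )
    pretty = ", ".join(f"{c}={m:.2f}" for c, m in zip(TRAIT_CODES, mat.mean(axis=0)))
    print(f"{cond:8s} mean intensities: {pretty}")

write_trait_table(records, "scratch_field.csv")
print("wrote scratch_field.csv (standard trait-table layout)")
# Healthy plants show high colour/area/texture scores and a low wilting
# index; severe stress inverts that pattern.
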