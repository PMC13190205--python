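"""Stage field zones as Healthy / Mild Stress / Severe Stress.

Within a zone, healthy plants look alike: mean pairwise PGK similarity
is high.  Stress increases heterogeneity, so similarity falls;
thresholds (0.80, 0.60) convert it into a three-way status.
"""

from pgk import field_report, generate_field, stage_zones

records = generate_field(seed=7)
reports = stage_zones(records, assume_perceptual=True)
rep = field_report(reports)

print(rep.table.head(10).to_string(index=False))
print("...")
print("status counts:", rep.table["status"].value_counts().to_dict())
rep.heatmap("scratch_zones.png")
print("wrote scratch_zones.png (acre x zone similarity heatmap)")
# A similarity near 1.0 means the zone's three plants carry nearly
# identical trait-deviation graphs; below 0.60 the zone is flagged as
# severely stressed.
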