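"""Centerline morphometrics over the seven characteristic tracts.

For every geometry the centerline tree is split into total, ascending,
arch, descending, BCA, LCCA and LSA tracts; each tract gets length,
tortuosity (length/chord, >= 1), inscribed radius, curvature and torsion
statistics. Shapes are ranked by their maximum percent deviation from the
template to pick representatives for simulation.
"""

import aortaflow as af
from aortaflow import morphometry as mm
from aortaflow import ssm

cohort = af.sample_population(af.PopulationSpec(n_subjects=19, seed=42))
model = ssm.fit_pca(cohort, n_modes=19)
augmented = ssm.augment_dataset(model)

tracts = {g.label: af.split_tracts(g.centerline_tree) for g in augmented}
table = mm.compare_to_template(mm.feature_table(tracts))

tmpl = table[(table.label == "template")].set_index("tract")
print("template tract morphometrics:")
for name in ("ascending", "arch", "descending"):
    row = tmpl.loc[name]
    print(f"  {name:10s} length {row.length:6.1f} mm   tortuosity {row.tortuosity:.3f}"
          f"   radius {row.radius_mean:5.2f} mm   curvature {row.curvature_mean:.4f} 1/mm")

selected = mm.select_representatives(table, k=20, mode_limit=10)
print(f"\nselected for healthy simulation ({len(selected)} incl. template):")
print(" ", ", ".join(selected))

planes = mm.define_result_planes(tracts["template"])
for p in planes:
    print(f"result plane {p.name:10s} origin {p.origin.round(1)} mm")
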