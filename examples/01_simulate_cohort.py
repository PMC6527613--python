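"""Generate a small synthetic polar-map cohort and inspect its structure.

Builds 20 rest maps (10 normal / 10 abnormal with territory-confined
perfusion defects), writes them to CSV, and prints per-class uptake
statistics.  The printed contrast shows what the classifiers exploit:
abnormal maps carry a contiguous low-uptake region inside one coronary
territory while global statistics stay similar.
"""

import numpy as np

import polargcn as pg

cfg = pg.SyntheticConfig(n_normal=10, n_abnormal=10, condition="rest", seed=42)
cohort = pg.generate_cohort(cfg)
pg.write_polarmap_table(pg.cohort_maps(cohort), "example_cohort.csv")

grid = pg.PolarGrid()
for sample in cohort[:4]:
    pm = sample.polar_map
    flagged = [int(s) for s in np.flatnonzero(sample.segment_truth) + 1]
    if len(flagged):
        nodes = np.concatenate([grid.nodes_of_segment(s) for s in flagged])
        lesion_mean = pm.values[nodes].mean()
    else:
        lesion_mean = float("nan")
    print(
        f"{pm.sample_id}: label={pm.label:8s} global mean uptake={pm.values.mean():.3f} "
        f"defect segments={list(flagged)} lesion mean={lesion_mean:.3f}"
    )

print("\nwrote example_cohort.csv —", len(cohort), "maps, 460 values each.")
print("Lesion means sit well below the ~0.8 global level: that localized")
print("deficit, not the global mean, separates the classes.")
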