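"""Neighbor-referenced apical area and junction-intensity ratios on a
simulated en-face mosaic.

Differentiating cells are constricted to half their footprint and carry
half the junction-marker intensity; both factors are recovered as ratios
against four non-transfected neighbors one cell row away.
"""

import ntquant as nq
from ntquant.apical import estimate_junction_background

params = nq.MosaicSimParams(shape=(360, 360), n_cells=200,
                            constriction_scale=0.5, junction_factor=0.5,
                            seed=2)
label, junction, truth = nq.generate_apical_mosaic(params)

cells = nq.measure_apical_cells(label, junction,
                                flags=truth[["cell_id", "transfected"]])
graph = nq.build_adjacency(label)
kept = nq.pair_filter(cells, graph)           # discard adjacent sister pairs
background = estimate_junction_background(label, junction)
ratios = nq.neighbor_ratio_table(kept, graph, background=background)

merged = ratios.merge(truth[["cell_id", "differentiating"]], on="cell_id")
for diff, group in merged.groupby("differentiating"):
    kind = "differentiating" if diff else "non-differentiating"
    print(f"{kind:22s} n={len(group):3d}  "
          f"area ratio {group['area_ratio'].mean():.3f}  "
          f"junction ratio {group['junction_ratio'].mean():.3f}")

labels, threshold = nq.split_small_large(
    merged["area_ratio"], merged.loc[~merged["differentiating"], "area_ratio"])
table, means = nq.crosstab_tuj1(labels, merged["differentiating"],
                                merged["area_ratio"])
print(f"\ncontrol-median threshold: {threshold:.3f}")
print(table)
print("\nDifferentiating cells recover the generative factors (0.5 each)")
print("and concentrate in the 'small' class below the control median.")
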