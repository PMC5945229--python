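"""End-to-end pipeline on a seeded synthetic bundle.

Simulates a section and an apical mosaic, then runs
measure -> classify -> normalize -> apical metrics -> statistics, writing
five CSV tables plus a manifest with the config hash and table checksums.
Rerunning with the same config reproduces identical bytes.
"""

import json

import ntquant as nq

config = nq.RunConfig(
    seed=7, out_dir="example_output/pipeline_run",
    section={"n_nuclei": 150, "shape": (300, 300), "transfected_fraction": 0.4},
    mosaic={"n_cells": 150, "shape": (300, 300),
            "constriction_scale": 0.6, "junction_factor": 0.6})

result = nq.run_pipeline(config)
print("output tables:")
for name, path in sorted(result["paths"].items()):
    print(f"  {name:15s} {len(result['tables'][name]):4d} rows  -> {path}")
print("\nmanifest:")
print(json.dumps(result["manifest"], indent=2)[:400], "...")

stats = result["tables"]["stats"]
print("\npopulation comparison of normalized reporter intensity:")
print(stats[["group_a", "group_b", "p_adj", "stars"]].to_string(index=False))
print("\nNeurons sit at 0, progenitors at 1 on the normalized scale, so the")
print("three populations separate strongly in the Dunn pairwise table.")
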