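"""Cumulative-labeling time-course of a birth-dated cohort.

A cohort labeled at its division (t0) is followed under cumulative EdU
pulses (starting 3 h after labeling, then every 4 h).  Cells that keep
cycling become EdU+; cells that exit at t0 stay EdU- and turn on the
neuronal marker later.  The EdU+ plateau therefore reads out one minus the
cycle-exit fraction.
"""

import ntquant as nq

params = nq.CohortSimParams(n_cells=500, exit_fraction=0.35, seed=3)
cohort, truth = nq.generate_cohort_timecourse(params)
curve = nq.cumulative_labeling_curve(cohort, plateau_onset_h=12.0)

print(curve.table.to_string(index=False,
                            formatters={"frac_edu": "{:.3f}".format,
                                        "frac_hucd": "{:.3f}".format}))
print(f"\nEdU+ plateau (t >= 12 h): {curve.plateau:.3f}"
      f"   (generative 1 - exit fraction = {1 - params.exit_fraction:.2f})")
print(f"plateau flatness:         {curve.flatness:.3f}")
print("\nThe plateau sits near 0.65: about a third of the cohort exited the")
print("cycle at t0, the regime of a neurogenic-stage labeling experiment.")
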