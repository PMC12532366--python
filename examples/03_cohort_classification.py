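"""Leave-one-replicate-out SVM classification of a synthetic cohort.

Simulates an amyloidosis-model cohort (4 transgenic and 4 control
replicates, 5 spots each, 5 repeated tomographies per spot) in which
transgenic tissue preserves entanglement better (Werner p ~ 0.95) than
control tissue (p ~ 0.75), then trains a linear SVM on (tangle, linear
entropy) holding out one replicate pair at a time.
"""

from entsense import simulate_cohort
from entsense.classify import (
    assemble_features,
    compare_1d_2d,
    leave_one_replicate_out,
    split_results_frame,
)
from entsense.pipeline import measure_cohort
from entsense.simulate import GroupSpec, SyntheticCohortConfig

cfg = SyntheticCohortConfig(
    groups=(
        GroupSpec("5xFAD", "hippocampus", "transgenic", 0.95, 0.02),
        GroupSpec("CD1", "hippocampus", "control", 0.75, 0.02),
    ),
    seed=11,
)
spots = simulate_cohort(cfg)
measurements = measure_cohort(spots)
records = assemble_features(measurements, ("5xFAD", "CD1"), "hippocampus")

results = leave_one_replicate_out(records, seed=11)
frame = split_results_frame(results)
cols = ["held_out_replicate", "selected_C", "precision", "recall",
        "sensitivity", "specificity", "f1"]
print(frame[cols].to_string(index=False))

comp = compare_1d_2d(records, seed=11)
print("\n2D (tangle, linear entropy) vs 1D (Werner p) mean F1:",
      f"{comp['2d_f1'].mean():.3f} vs {comp['1d_f1'].mean():.3f}")
print("\nEach row holds out one biological replicate entirely; metrics of 1")
print("in every split mean the decision boundary generalizes to unseen mice.")
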