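"""Effect of the number of surface patches on classification performance.

Sweeps the k-means partition count over {5, 10, 20, 50, 100, 200, 300} and
evaluates the displacement biomarker at each value (5 seeded hold-out runs).
Coarse patches average the focal atrophy signal away; fine patches keep it,
so the weighted AUC should not degrade as N grows toward 300.
"""

from shapedx import RunConfig, run_partition_sweep
from shapedx.synthetic import CohortSpec, generate_cohort

spec = CohortSpec(seed=7, mesh_subdivisions=3, voxel_spacing=1.5)
cohort = generate_cohort(spec)

config = RunConfig(seed=42)
result = run_partition_sweep(cohort, config, n_seeds=5)
print(result.to_string(index=False))
print("\nmean weighted AUC at N=300 minus N=5:",
      round(result.set_index("n_patches").loc[300, "weighted_auc_mean"]
            - result.set_index("n_patches").loc[5, "weighted_auc_mean"], 3))
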