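"""The complete two-branch study at the published design sizes.

Training branch (100 disease / 44 healthy) builds the mask and the
decoder; the testing branch (19 / 20, different age structure) is only
scored.  Prints the confusion table, the five diagnostic metrics, and
the Mann-Whitney comparison of decision scores.
"""

import json

from petmvpa import CohortSpec, RunConfig, run_all
from petmvpa.pipeline import default_clusters

clusters = default_clusters(0.3)
config = RunConfig(
    train_spec=CohortSpec(n_disease=100, n_healthy=44, clusters=clusters, seed=None),
    test_spec=CohortSpec(n_disease=19, n_healthy=20,
                         age_mean_disease=42.5, age_sd_disease=15.0,
                         age_mean_healthy=52.0, age_sd_healthy=15.0,
                         clusters=clusters, seed=None),
    seed=1,
)
artifacts, report = run_all(config)

print(f"mask: {artifacts.mask.n_voxels} voxels in "
      f"{len(artifacts.mask.report)} clusters\n")
print(report.cm.as_table())
print("\nmetrics (%):", json.dumps(report.metrics.as_percent(decimals=1)))
print("Mann-Whitney on testing scores:", report.mann_whitney)
print("\nWith a strong planted effect (30% reduction) the held-out subjects")
print("separate essentially perfectly; lower the effect_fraction to see the")
print("metrics degrade toward the mixed regime real cohorts live in.")
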