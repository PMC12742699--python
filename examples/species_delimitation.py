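"""Unsupervised species delimitation on synthetic two-species data.

Generates the default two-species worker table (40 + 46 nests, 3 minor
workers each), runs nest-centroid Ward clustering with both partitioning
routes, resolves wild cards by confirmative stepwise LDA, and compares the
recovered labels with the generator's truth.
"""

import pandas as pd

from ncmorph import PipelineConfig, SynthConfig, generate_specimens, run_full

synth = SynthConfig(seed=1)
records, truth = generate_specimens(synth)
print(f"generated {len(records)} workers in {records['nest_id'].nunique()} nests; "
      f"worker-level Bayes error {100 * truth['bayes_error_worker']:.3f}%\n")

results = run_full(PipelineConfig(out_dir="scratch/delimitation_report", seed=1),
                   records=records)

parts = results["partitions"]
print(f"cluster count: hclust k={parts.k_hclust}, kmeans k={parts.k_kmeans}")
print(f"wild cards (routes disagree): {len(parts.wildcards)} of "
      f"{len(parts.concordant)} nests")
print("\nresubstitution error of the confirmative discriminant "
      "(score sign vs assigned group):")
print(results["error_rates"].to_string(index=False))

final = results["final_labels"]
species = pd.Series(truth["nest_species"]).reindex(final.index)
print("\nrecovered clusters vs true species:")
print(pd.crosstab(final, species).to_string())
print("\n(a clean diagonal means the unsupervised pipeline rediscovered the "
      "two species; the discriminant separates them with the boundary at "
      "score 0)")
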