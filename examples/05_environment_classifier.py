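"""Random-forest classification of source samples into environments.

One environment is tested against all others pooled as 'other' (500
trees, fixed random state, out-of-bag scoring), reporting held-out
accuracy from a ~3:1 stratified split and the most discriminative taxa.
"""

from metatracker.envclassify import classify, make_labels
from metatracker.synthdata import generate_study

study = generate_study("coastal-small", seed=7)
sources = study.metadata[study.metadata["role"] == "source"]

for env in study.env_profiles.columns:
    labels = make_labels(sources, env)
    report = classify(study.table, labels, n_trees=500, seed=0)
    print(f"{env:<15} accuracy={report.accuracy:.3f} "
          f"oob_error={report.oob_error:.3f}")

labels = make_labels(sources, "coastal_marine")
report = classify(study.table, labels, n_trees=500, seed=0)
print("\ntop discriminative taxa for coastal_marine (mean impurity decrease):")
for taxon, importance in report.top_features[:5]:
    print(f"  {taxon}  {importance:.4f}")
print("\nAccuracy is the held-out fraction classified correctly; OOB error "
      "is the forest's internal generalization estimate. Well-separated "
      "environments classify near-perfectly.")
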