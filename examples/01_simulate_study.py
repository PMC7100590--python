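"""Generate a synthetic multi-environment study with known mixing truth.

The generator emulates a coastal-marine source-tracking design: five
source environments with realistic per-environment sample counts, plus
fourteen sink samples whose true source mixtures are recorded.
"""

from metatracker.synthdata import generate_study

study = generate_study("coastal-small", seed=7, out_dir="scratch/study")

print(f"feature table: {study.table.n_taxa} taxa x {study.table.n_samples} samples")
print(study.metadata["role"].value_counts().to_string())
print("\ntrue mixing vectors of the first three sinks:")
print(study.truth.head(3).round(3).to_string())
print("\nEach truth row sums to 1: the fraction of the sink's reads drawn "
      "from each source environment (last column = the withheld 'unknown' "
      "profile no source sample covers).")
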