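"""Generate a synthetic benchmark with known biomarkers and write it out.

The mixture benchmark (S2) has 1,000 taxa over 100 samples in two classes
of two subclasses each: 10 redundant groups of 10 positive markers whose
distribution differs between classes, plus 900 background taxa that carry
no class signal.  The ground-truth table records every feature's group.
"""

from pathlib import Path

from metaboot import generate_s2, write_dataset

dataset = generate_s2(seed=7)
table = dataset.table
print(f"matrix: {table.n_features} features x {table.n_samples} samples")
print(f"positive markers: {dataset.truth.n_positive} "
      f"(in {len({g for g, p in zip(dataset.truth.group_ids, dataset.truth.is_positive) if p})} groups)")
print(f"classes: {dataset.metadata.classes}, "
      f"strata: {sorted(set(dataset.metadata.strata()))}")

out = Path("scratch/s2_demo")
write_dataset(dataset, out)
print(f"wrote abundance.tsv, metadata.tsv, ground_truth.tsv -> {out}/")
# The three TSVs are everything a selection run needs; is_positive = 1
# marks the features a perfect method would recover.
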