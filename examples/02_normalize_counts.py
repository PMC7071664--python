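"""Library-size normalization of family counts.

Counts are divided by each sample's total ORF count and rescaled by the
smallest library in the normalization group, so the shallowest sample
keeps its raw counts.
"""

import pandas as pd

from holocaz import FamilyCountMatrix, SampleMeta, normalize_counts

raw = pd.DataFrame(
    {"deep_sample": [10, 40], "shallow_sample": [10, 40]},
    index=["GH13", "GT2"],
)
meta = [
    SampleMeta("deep_sample", "P. dilatatus dilatatus", "laboratory", "male",
               "hindgut", "metagenome", n_orfs=400_000),
    SampleMeta("shallow_sample", "A. aquaticus", "laboratory", "male",
               "hindgut", "metagenome", n_orfs=200_000),
]

matrix = normalize_counts(FamilyCountMatrix(raw=raw), meta)
print(matrix.normalized.round(2))
ref = matrix.group_reference["metagenome"]
print(f"\ngroup reference = {ref.reference_n_orfs} ORFs "
      f"(minimum over {list(ref.member_samples)})")
print("The deep sample's counts are halved: it has twice the ORFs, so the")
print("same raw count means half the relative abundance.")
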