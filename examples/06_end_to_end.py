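"""Simulate a holobiont dataset with planted loci and run the full
pipeline, then score the results against the ground truth."""

import json
import tempfile
from pathlib import Path

from holocaz import SyntheticScenario, generate, score_against_truth
from holocaz.pipeline import RunConfig, headline_summary, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    scenario = SyntheticScenario(seed=1)  # 5 PULs, 50 decoys, 30 fusions
    manifest = generate(scenario, tmp / "data")
    bundle = run_pipeline(RunConfig(input_dir=tmp / "data",
                                    out_dir=tmp / "out"))

    print("headline summary:")
    print(json.dumps(headline_summary(bundle), indent=1, sort_keys=True))

    print("\nrecovery vs planted truth:")
    for stage, s in score_against_truth(bundle.as_outputs(), manifest).items():
        print(f"  {stage:12s} precision={s.precision} recall={s.recall} "
              f"exact={s.exact}")

print("\nLocus screens are exact (Pfam markers are deterministic evidence);")
print("consensus recall sits near q^3 = 0.512 for the background CAZymes")
print("because all three tools must independently agree (q = 0.8 each).")
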