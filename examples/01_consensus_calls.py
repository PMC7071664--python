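"""Three-tool consensus CAZyme calling on a handful of ORFs.

An ORF's family assignment is kept only when the profile-HMM, sequence-
similarity and peptide-signature streams all report it; module counts come
from the HMM stream (domains, not genes).
"""

from holocaz import DomainHit, Tool, call_consensus

hits = [
    # orf_1: full agreement on GH13, two HMM domains -> module_count 2
    DomainHit("orf_1", Tool.HMM, "GH13", 1e-60, (10, 110)),
    DomainHit("orf_1", Tool.HMM, "GH13", 1e-40, (150, 250)),
    DomainHit("orf_1", Tool.SIMILARITY, "GH13", 1e-80),
    DomainHit("orf_1", Tool.PEPTIDE, "GH13", 12.0),
    # orf_2: only two tools agree -> partial evidence, never counted
    DomainHit("orf_2", Tool.HMM, "GH5_13", 1e-30),
    DomainHit("orf_2", Tool.SIMILARITY, "GH5_4", 1e-70),
    # orf_3: agreement at family level despite subfamily disagreement
    DomainHit("orf_3", Tool.HMM, "GH5_13", 1e-35),
    DomainHit("orf_3", Tool.SIMILARITY, "GH5_4", 1e-65),
    DomainHit("orf_3", Tool.PEPTIDE, "GH5", 9.0),
]

result = call_consensus(hits, sample_id="demo")
for c in result.calls:
    print(f"call    {c.orf_id}  {c.family}  modules={c.module_count}")
for p in result.partial:
    tools = ",".join(sorted(t.value for t in p.evidence))
    print(f"partial {p.orf_id}  {p.family}  seen by [{tools}] only")

print()
print("Two consensus calls survive the intersection rule; orf_2 stays in")
print("the partial side channel because the peptide stream never saw GH5.")
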