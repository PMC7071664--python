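"""Three-tool consensus CAZyme calling and family counting.

A CAZyme call is accepted only when all three evidence streams (profile-HMM,
sequence similarity, peptide signature) report the same CAZy family on the
same ORF — the conservative intersection rule. "CAZyme" counts are counts of
functional modules (domains), not genes: the module count of a call is the
number of HMM-stream domain hits of that family on the ORF, because the
HMM stream is the one with per-domain resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from holocaz.model import DomainHit, SampleMeta, Tool, family_of, is_cazy_label
from holocaz.quantify import FamilyCountMatrix


@dataclass(frozen=True)
class CazymeCall:
    """One consensus (ORF, CAZy family) assignment.

    ``evidence`` is the set of tools that reported the family; a consensus
    call has all three. ``module_count`` is the number of HMM-evidence
    domains of this family on the ORF (>= 1).
    """

    orf_id: str
    family: str
    evidence: frozenset[Tool]
    module_count: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.module_count < 1:
            raise ValueError("module_count must be >= 1")


@dataclass
class PartialCall:
    """A non-consensus (ORF, family) pair kept for reporting, never counted."""

    orf_id: str
    family: str
    evidence: frozenset[Tool]
    sample_id: str = ""


@dataclass
class ConsensusResult:
    """Consensus calls plus the partial-evidence side channel."""

    calls: list[CazymeCall]
    partial: list[PartialCall] = field(default_factory=list)

    def __iter__(self):
        return iter(self.calls)

    def __len__(self) -> int:
        return len(self.calls)


def call_consensus(
    hits: Iterable[DomainHit],
    similarity_evalue_max: float = 1e-50,
    peptide_min_score: Optional[float] = None,
    subfamily: bool = False,
    sample_id: str = "",
) -> ConsensusResult:
    """Apply the three-tool intersection rule to per-ORF domain evidence.

    Agreement is evaluated at family level by default (``GH5_13`` and
    ``GH5_4`` both agree at ``GH5``) because the evidence streams differ in
    subfamily resolution; pass ``subfamily=True`` to require exact label
    agreement. Similarity hits pass an E-value gate (default 1e-50);
    peptide hits are unfiltered unless ``peptide_min_score`` is set. Pfam
    (non-CAZy) hits are ignored here.

    Returns consensus calls, with every non-consensus (ORF, family) pair —
    any pair seen by one or two tools only — retained in the ``partial``
    side channel with its partial evidence.
    """
    resolve = (lambda lab: lab) if subfamily else family_of
    evidence: dict[tuple[str, str], set[Tool]] = {}
    hmm_modules: dict[tuple[str, str], int] = {}
    for hit in hits:
        if not is_cazy_label(hit.label):
            continue
        if hit.source_tool is Tool.SIMILARITY and hit.evalue > similarity_evalue_max:
            continue
        if (
            hit.source_tool is Tool.PEPTIDE
            and peptide_min_score is not None
            and hit.evalue < peptide_min_score
        ):
            continue
        key = (hit.orf_id, resolve(hit.label))
        evidence.setdefault(key, set()).add(hit.source_tool)
        if hit.source_tool is Tool.HMM:
            hmm_modules[key] = hmm_modules.get(key, 0) + 1
    all_tools = {Tool.HMM, Tool.SIMILARITY, Tool.PEPTIDE}
    calls: list[CazymeCall] = []
    partial: list[PartialCall] = []
    for key in sorted(evidence):
        orf_id, fam = key
        tools = evidence[key]
        if tools == all_tools:
            calls.append(
                CazymeCall(
                    orf_id=orf_id,
                    family=fam,
                    evidence=frozenset(tools),
                    module_count=max(hmm_modules.get(key, 1), 1),
                    sample_id=sample_id,
                )
            )
        else:
            partial.append(PartialCall(orf_id, fam, frozenset(tools), sample_id))
    return ConsensusResult(calls=calls, partial=partial)


def count_families(
    calls: Iterable[CazymeCall],
    samples: Union[Sequence[SampleMeta], Sequence[str]],
) -> FamilyCountMatrix:
    """Tally module counts into a family x sample matrix.

    Cell (family, sample) is the sum of ``module_count`` over calls of that
    family in that sample; samples with no calls yield all-zero columns. A
    call referencing a sample outside the declared universe is fatal.
    """
    sample_ids = [s.sample_id if isinstance(s, SampleMeta) else s for s in samples]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids in sample universe")
    tallies: dict[tuple[str, str], int] = {}
    known = set(sample_ids)
    for call in calls:
        if call.sample_id not in known:
            raise ValueError(f"call references unknown sample {call.sample_id!r}")
        key = (call.family, call.sample_id)
        tallies[key] = tallies.get(key, 0) + call.module_count
    families = sorted({fam for fam, _ in tallies})
    raw = pd.DataFrame(0, index=families, columns=sample_ids, dtype=int)
    for (fam, sid), count in tallies.items():
        raw.loc[fam, sid] = count
    return FamilyCountMatrix(raw=raw)


@dataclass(frozen=True)
class FamilyPartition:
    """Set partition of CAZy families between host and microbiota."""

    host_only: frozenset[str]
    microbiota_only: frozenset[str]
    shared: frozenset[str]

    @property
    def union_size(self) -> int:
        return len(self.host_only) + len(self.microbiota_only) + len(self.shared)


def partition_families(
    meta_families: Iterable[str], host_families: Iterable[str]
) -> FamilyPartition:
    """Partition family sets into host-only, microbiota-only and shared.

    Satisfies |host_only| + |microbiota_only| + |shared| = |union|.
    """
    meta = frozenset(meta_families)
    host = frozenset(host_families)
    return FamilyPartition(
        host_only=host - meta,
        microbiota_only=meta - host,
        shared=meta & host,
    )
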