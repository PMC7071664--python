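"""Library-size normalization of family count matrices.

Raw module counts are not comparable across samples because assemblies
differ in depth. Each sample's counts are divided by its total ORF count
(relative abundance) and rescaled by the smallest ORF count within its
normalization group, so the group's shallowest library keeps its raw
counts and deeper libraries are scaled down proportionally:

    normalized(f, s) = raw(f, s) / n_orfs(s) * min_{s' in group(s)} n_orfs(s')

Groups default to ``dataset_kind`` strata (metagenomes and transcriptomes
are never normalized against one another); any partition of the samples
may be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from holocaz.model import SampleMeta, cazy_class


@dataclass(frozen=True)
class NormalizationReference:
    """The reference library size of one normalization group.

    ``reference_n_orfs`` is the minimum ``n_orfs`` over the group members.
    """

    group_id: str
    reference_n_orfs: int
    member_samples: tuple[str, ...]


@dataclass
class FamilyCountMatrix:
    """Family x sample module counts, raw and (optionally) normalized.

    ``raw`` is a non-negative integer DataFrame indexed by family label
    with one column per sample. ``normalized`` shares its shape and is
    populated by :func:`normalize_counts`; values are kept unrounded.
    """

    raw: pd.DataFrame
    normalized: Optional[pd.DataFrame] = None
    group_reference: dict[str, NormalizationReference] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.raw.to_numpy() < 0).any():
            raise ValueError("raw counts must be non-negative")
        if self.normalized is not None and self.normalized.shape != self.raw.shape:
            raise ValueError("normalized matrix shape differs from raw")

    @property
    def families(self) -> list[str]:
        return list(self.raw.index)

    @property
    def samples(self) -> list[str]:
        return list(self.raw.columns)

    def class_marginals(self, normalized: bool = False) -> pd.DataFrame:
        """Per-CAZy-class (GH/GT/PL/CE/AA/CBM) column sums."""
        source = self._pick(normalized)
        classes = pd.Index([cazy_class(f) for f in source.index], name="cazy_class")
        return source.groupby(classes).sum()

    def family_totals(self, normalized: bool = False) -> pd.Series:
        return self._pick(normalized).sum(axis=1)

    def _pick(self, normalized: bool) -> pd.DataFrame:
        if normalized:
            if self.normalized is None:
                raise ValueError("matrix has not been normalized yet")
            return self.normalized
        return self.raw

    def to_tsv(self, path, normalized: bool = False) -> None:
        self._pick(normalized).to_csv(path, sep="\t", index_label="family")

    @classmethod
    def from_tsv(cls, path) -> "FamilyCountMatrix":
        raw = pd.read_csv(path, sep="\t", index_col="family")
        return cls(raw=raw)


def default_groups(meta: Iterable[SampleMeta]) -> dict[str, list[str]]:
    """Group samples by dataset kind (metagenome vs transcriptome)."""
    groups: dict[str, list[str]] = {}
    for m in meta:
        groups.setdefault(m.dataset_kind, []).append(m.sample_id)
    return groups


def normalize_counts(
    matrix: FamilyCountMatrix,
    meta: Sequence[SampleMeta],
    groups: Optional[Mapping[str, Sequence[str]]] = None,
) -> FamilyCountMatrix:
    """Normalize a count matrix by ORF library size within groups.

    Returns a new matrix with ``normalized`` filled and ``raw`` untouched.
    Every sample column must belong to exactly one group and have a
    positive ``n_orfs``; the group reference is the minimum member
    ``n_orfs``.
    """
    n_orfs = {m.sample_id: m.n_orfs for m in meta}
    for sid in matrix.samples:
        if sid not in n_orfs:
            raise ValueError(f"sample {sid!r} missing from metadata")
        if n_orfs[sid] <= 0:
            raise ValueError(f"sample {sid!r} has non-positive n_orfs")
    if groups is None:
        groups = default_groups([m for m in meta if m.sample_id in set(matrix.samples)])
    assignment: dict[str, str] = {}
    for gid, members in groups.items():
        for sid in members:
            if sid in assignment:
                raise ValueError(f"sample {sid!r} appears in multiple groups")
            assignment[sid] = gid
    missing = [s for s in matrix.samples if s not in assignment]
    if missing:
        raise ValueError(f"samples missing from normalization groups: {missing}")
    references: dict[str, NormalizationReference] = {}
    for gid, members in groups.items():
        members = tuple(m for m in members if m in set(matrix.samples))
        if not members:
            continue
        references[gid] = NormalizationReference(
            group_id=gid,
            reference_n_orfs=min(n_orfs[m] for m in members),
            member_samples=members,
        )
    normalized = matrix.raw.astype(float).copy()
    for sid in matrix.samples:
        ref = references[assignment[sid]].reference_n_orfs
        normalized[sid] = matrix.raw[sid] / n_orfs[sid] * ref
    return replace(matrix, normalized=normalized, group_reference=references)
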