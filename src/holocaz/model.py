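"""Core data model shared across the pipeline.

Coordinates are 1-based inclusive throughout (GFF convention).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Optional

#: CAZy class prefixes: glycoside hydrolases, glycosyltransferases,
#: polysaccharide lyases, carbohydrate esterases, auxiliary activities,
#: carbohydrate-binding modules.
CAZY_CLASSES = ("GH", "GT", "PL", "CE", "AA", "CBM")

#: Canonical taxonomy ranks, domain downward.
CANONICAL_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

_CAZY_RE = re.compile(r"^(GH|GT|PL|CE|AA|CBM)(\d+)(?:_(\d+))?$")
_PFAM_RE = re.compile(r"^PF\d{5}$")


class Tool(str, enum.Enum):
    """Evidence stream a domain hit came from.

    ``hmm``: profile-HMM domain search against a CAZyme domain database;
    ``similarity``: sequence-similarity search against annotated CAZyme
    sequences; ``peptide``: conserved short-peptide signature search.
    """

    HMM = "hmm"
    SIMILARITY = "similarity"
    PEPTIDE = "peptide"


def is_cazy_label(label: str) -> bool:
    """True for a canonical CAZy family or subfamily label, e.g. ``GH13``, ``GH5_13``."""
    return bool(_CAZY_RE.match(label))


def is_pfam_accession(label: str) -> bool:
    """True for a versionless Pfam accession, e.g. ``PF07980``."""
    return bool(_PFAM_RE.match(label))


def canonicalize_label(raw: str) -> Optional[str]:
    """Canonicalize a tool-reported label, or return None if unrecognized.

    Strips trailing ``.hmm`` suffixes and Pfam version suffixes
    (``PF00593.25`` -> ``PF00593``); CAZy subfamily suffixes are preserved
    (``GH5_13`` stays ``GH5_13``).
    """
    label = raw.strip()
    if label.endswith(".hmm"):
        label = label[: -len(".hmm")]
    if is_cazy_label(label):
        return label
    head = label.split(".", 1)[0]
    if is_pfam_accession(head):
        return head
    return None


def family_of(label: str) -> str:
    """Collapse a CAZy subfamily label to its family: ``GH5_13`` -> ``GH5``."""
    m = _CAZY_RE.match(label)
    if not m:
        raise ValueError(f"not a CAZy label: {label!r}")
    return f"{m.group(1)}{m.group(2)}"


def cazy_class(label: str) -> str:
    """CAZy class prefix of a family label: ``GH13`` -> ``GH``."""
    m = _CAZY_RE.match(label)
    if not m:
        raise ValueError(f"not a CAZy label: {label!r}")
    return m.group(1)


@dataclass(frozen=True)
class DomainHit:
    """One domain-evidence record for an ORF.

    ``label`` is a CAZy family/subfamily (``GH13``, ``GH5_13``) or a Pfam
    accession (``PF07980``). ``evalue`` is the hit E-value for HMM and
    similarity streams; for the peptide stream it stores the (non-negative)
    signature score, which has no E-value semantics. ``coords`` are 1-based
    inclusive amino-acid positions within the ORF, when the source reports
    them.
    """

    orf_id: str
    source_tool: Tool
    label: str
    evalue: float
    coords: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"evalue must be >= 0, got {self.evalue}")
        if not self.label:
            raise ValueError("label must be non-empty")
        if not (is_cazy_label(self.label) or is_pfam_accession(self.label)):
            raise ValueError(f"unrecognized label: {self.label!r}")


@dataclass
class GeneOnContig:
    """A gene model placed on an assembled contig.

    ``gene_index`` is the 1-based rank of the gene along the contig by
    ascending start coordinate; locus screens evaluate adjacency on it.
    ``domains`` holds conserved-domain (Pfam) hits attached to the gene;
    ``cazy_families`` holds consensus CAZy family labels.
    """

    contig_id: str
    gene_index: int
    start: int
    end: int
    strand: str
    orf_id: str
    domains: frozenset[DomainHit] = field(default_factory=frozenset)
    cazy_families: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"start > end for {self.orf_id} ({self.start} > {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def domain_accessions(self) -> frozenset[str]:
        return frozenset(h.label for h in self.domains)


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata and library size.

    ``n_orfs`` is the total number of ORFs predicted in the sample's
    assembly — the library-size denominator for count normalization.
    """

    sample_id: str
    host_species: str
    origin: str  # laboratory | field
    sex: str  # male | female
    tissue: str  # caeca | hindgut | non_digestive | whole
    dataset_kind: str  # metagenome | transcriptome
    n_orfs: int

    _ORIGINS = ("laboratory", "field")
    _SEXES = ("male", "female")
    _TISSUES = ("caeca", "hindgut", "non_digestive", "whole")
    _KINDS = ("metagenome", "transcriptome")

    def __post_init__(self) -> None:
        if self.n_orfs <= 0:
            raise ValueError(f"n_orfs must be positive, got {self.n_orfs}")
        if self.origin not in self._ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r}")
        if self.sex not in self._SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.tissue not in self._TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")
        if self.dataset_kind not in self._KINDS:
            raise ValueError(f"unknown dataset_kind {self.dataset_kind!r}")


@dataclass(frozen=True)
class TaxonLineage:
    """One ranked taxonomy hit for an ORF.

    ``lineage`` is an ordered tuple of (rank_name, taxon_name) pairs from
    domain downward; ``hit_rank`` is the 1-based rank of the hit among the
    retained top-k hits (best score first).
    """

    orf_id: str
    hit_rank: int
    lineage: tuple[tuple[str, str], ...]
    bitscore_or_evalue: float = 0.0

    def __post_init__(self) -> None:
        if not self.lineage:
            raise ValueError("lineage must be non-empty")
        known = [r for r, _ in self.lineage if r in CANONICAL_RANKS]
        order = [CANONICAL_RANKS.index(r) for r in known]
        if order != sorted(order):
            raise ValueError(f"lineage ranks out of canonical order: {known}")

    def name_at(self, rank: str) -> Optional[str]:
        for r, name in self.lineage:
            if r == rank:
                return name
        return None
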