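"""Readers and writers for the pipeline's external table formats.

Three domain-evidence dialects are supported, each defined by a documented
column schema (no format sniffing):

``hmm_domtbl``
    HMMER3 ``--domtblout`` layout: whitespace-delimited, 22 fixed columns
    plus a free-text description. Works for both search directions — the
    side (target or query) whose name/accession canonicalizes to a CAZy
    family or Pfam accession is taken as the label, the other as the ORF.
    E-value is the per-domain i-Evalue (column 13); coordinates are the
    alignment from/to (columns 18-19).

``similarity_tab``
    12-column BLAST/DIAMOND ``outfmt 6``: qseqid sseqid pident length
    mismatch gapopen qstart qend sstart send evalue bitscore. The query is
    the ORF; the subject id is either a plain family label or
    ``<seqid>|<label>[|...]`` with the family in a pipe-delimited segment.

``peptide_tab``
    3+ column TSV: orf_id, family, score. The score is a signature count,
    not an E-value; it is stored in the hit's ``evalue`` slot (non-negative,
    larger = stronger) and no threshold is applied by default.

Malformed rows are skipped with a :class:`ParserWarning` carrying the line
number in lenient mode (the default) and raise :class:`ParserError` in
strict mode. Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Iterable, Optional, Union

from holocaz.model import (
    CANONICAL_RANKS,
    DomainHit,
    GeneOnContig,
    SampleMeta,
    TaxonLineage,
    Tool,
    canonicalize_label,
)

PathLike = Union[str, Path]

DIALECTS = ("hmm_domtbl", "similarity_tab", "peptide_tab")


class ParserError(ValueError):
    """Fatal parse failure (strict mode, or an unusable file)."""


class ParserWarning(UserWarning):
    """A malformed row was skipped; the message carries the line number."""


def _reject(message: str, line_no: int, strict: bool) -> None:
    full = f"line {line_no}: {message}"
    if strict:
        raise ParserError(full)
    warnings.warn(full, ParserWarning, stacklevel=3)


# ---------------------------------------------------------------------------
# domain-evidence hits


def read_domain_hits(
    path: PathLike, dialect: str, strict: bool = False
) -> list[DomainHit]:
    """Read one evidence table into :class:`DomainHit` records.

    Labels are canonicalized (trailing ``.hmm`` stripped, Pfam versions
    stripped, subfamily suffixes preserved); rows whose label matches
    neither a CAZy family nor a Pfam accession are rejected.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ParserError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if not path.exists():
        raise ParserError(f"no such file: {path}")
    parser = {
        "hmm_domtbl": _parse_domtbl_row,
        "similarity_tab": _parse_outfmt6_row,
        "peptide_tab": _parse_peptide_row,
    }[dialect]
    hits: list[DomainHit] = []
    with path.open() as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            try:
                hits.append(parser(line))
            except ValueError as exc:
                _reject(str(exc), line_no, strict)
    return hits


def _parse_domtbl_row(line: str) -> DomainHit:
    fields = line.split()
    if len(fields) < 22:
        raise ValueError(f"expected >= 22 columns, got {len(fields)}")
    t_name, t_acc = fields[0], fields[1]
    q_name, q_acc = fields[3], fields[4]
    label = canonicalize_label(t_name) or canonicalize_label(t_acc)
    orf = q_name
    if label is None:
        label = canonicalize_label(q_name) or canonicalize_label(q_acc)
        orf = t_name
    if label is None:
        raise ValueError(
            f"no CAZy/Pfam label on either side ({t_name!r} / {q_name!r})"
        )
    evalue = float(fields[12])  # per-domain i-Evalue
    if evalue < 0:
        raise ValueError(f"negative E-value {evalue}")
    ali_from, ali_to = int(fields[17]), int(fields[18])
    return DomainHit(orf, Tool.HMM, label, evalue, (ali_from, ali_to))


def _parse_outfmt6_row(line: str) -> DomainHit:
    fields = line.split("\t") if "\t" in line else line.split()
    if len(fields) < 12:
        raise ValueError(f"expected 12 columns, got {len(fields)}")
    orf = fields[0]
    label = None
    for segment in fields[1].split("|"):
        label = canonicalize_label(segment)
        if label is not None:
            break
    if label is None:
        raise ValueError(f"no CAZy family in subject id {fields[1]!r}")
    evalue = float(fields[10])
    if evalue < 0:
        raise ValueError(f"negative E-value {evalue}")
    qstart, qend = int(fields[6]), int(fields[7])
    return DomainHit(orf, Tool.SIMILARITY, label, evalue, (qstart, qend))


def _parse_peptide_row(line: str) -> DomainHit:
    fields = line.split("\t") if "\t" in line else line.split()
    if len(fields) < 3:
        raise ValueError(f"expected >= 3 columns, got {len(fields)}")
    label = canonicalize_label(fields[1])
    if label is None:
        raise ValueError(f"unrecognized family label {fields[1]!r}")
    score = float(fields[2])
    if score < 0:
        raise ValueError(f"negative score {score}")
    return DomainHit(fields[0], Tool.PEPTIDE, label, score, None)


# ---------------------------------------------------------------------------
# gene tables (GFF3)


def read_gene_table(path: PathLike, strict: bool = False) -> list[GeneOnContig]:
    """Read a GFF3 gene table into per-contig ordered gene models.

    Genes are grouped per contig and ``gene_index`` is assigned by ascending
    start coordinate (ties broken by end, then orf_id), starting at 1 on
    each contig. Overlapping genes are allowed but flagged with a warning;
    duplicate orf_ids on one contig warn (fatal in strict mode).
    """
    path = Path(path)
    if not path.exists():
        raise ParserError(f"no such file: {path}")
    per_contig: dict[str, list[tuple[int, int, str, str]]] = {}
    with path.open() as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                _reject(f"expected 9 GFF3 columns, got {len(cols)}", line_no, strict)
                continue
            contig, _, _, start_s, end_s, _, strand, _, attrs = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                _reject(f"non-integer coordinates {start_s!r}/{end_s!r}", line_no, strict)
                continue
            if start > end:
                _reject(f"start > end ({start} > {end})", line_no, strict)
                continue
            if strand not in ("+", "-"):
                _reject(f"bad strand {strand!r}", line_no, strict)
                continue
            orf_id = _gff_attr(attrs, "ID")
            if orf_id is None:
                _reject("missing ID attribute", line_no, strict)
                continue
            per_contig.setdefault(contig, []).append((start, end, strand, orf_id))
    genes: list[GeneOnContig] = []
    for contig in sorted(per_contig):
        rows = sorted(per_contig[contig], key=lambda r: (r[0], r[1], r[3]))
        seen_ids: set[str] = set()
        prev_end = 0
        for idx, (start, end, strand, orf_id) in enumerate(rows, start=1):
            if orf_id in seen_ids:
                _reject(f"duplicate orf_id {orf_id!r} on contig {contig}", 0, strict)
            seen_ids.add(orf_id)
            if start <= prev_end:
                warnings.warn(
                    f"gene {orf_id} overlaps its predecessor on contig {contig}",
                    ParserWarning,
                    stacklevel=2,
                )
            prev_end = max(prev_end, end)
            genes.append(GeneOnContig(contig, idx, start, end, strand, orf_id))
    return genes


def write_gene_table(genes: Iterable[GeneOnContig], path: PathLike) -> None:
    """Write gene models as GFF3 (content round-trips through
    :func:`read_gene_table` for well-formed inputs)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig_id, g.start, g.end, g.orf_id)):
            fh.write(
                f"{g.contig_id}\tholocaz\tCDS\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.orf_id}\n"
            )


def _gff_attr(attrs: str, key: str) -> Optional[str]:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


# ---------------------------------------------------------------------------
# taxonomy lineages


def read_lineages(
    path: PathLike,
    top_k: int = 5,
    evalue_cutoff: float = 1e-4,
    strict: bool = False,
) -> list[TaxonLineage]:
    """Read per-ORF taxonomy hits, keeping the top-k best-scoring hits.

    Input is a TSV with columns orf_id, hit_rank, evalue, lineage, where
    the lineage is semicolon-delimited. Entries may be explicit
    ``rank:name`` pairs or bare names, in which case canonical ranks
    (domain, phylum, class, order, family, genus, species) are assigned by
    position. Hits with E-value above ``evalue_cutoff`` are dropped, the
    survivors sorted best-score (smallest E-value) first, and at most
    ``top_k`` retained per ORF; empty lineages are dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise ParserError(f"no such file: {path}")
    per_orf: dict[str, list[tuple[float, tuple[tuple[str, str], ...]]]] = {}
    order: list[str] = []
    with path.open() as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                _reject(f"expected 4 columns, got {len(cols)}", line_no, strict)
                continue
            orf_id, _, evalue_s, lineage_s = cols[0], cols[1], cols[2], cols[3]
            try:
                evalue = float(evalue_s)
            except ValueError:
                _reject(f"non-numeric evalue {evalue_s!r}", line_no, strict)
                continue
            if evalue > evalue_cutoff:
                continue
            lineage = parse_lineage(lineage_s)
            if not lineage:
                _reject("empty lineage", line_no, strict)
                continue
            if orf_id not in per_orf:
                order.append(orf_id)
            per_orf.setdefault(orf_id, []).append((evalue, lineage))
    out: list[TaxonLineage] = []
    for orf_id in order:
        ranked = sorted(per_orf[orf_id], key=lambda t: t[0])[:top_k]
        for rank_no, (evalue, lineage) in enumerate(ranked, start=1):
            out.append(TaxonLineage(orf_id, rank_no, lineage, evalue))
    return out


def parse_lineage(text: str) -> tuple[tuple[str, str], ...]:
    """Parse a semicolon-delimited lineage string into (rank, name) pairs."""
    pairs: list[tuple[str, str]] = []
    entries = [e.strip() for e in text.split(";") if e.strip()]
    for pos, entry in enumerate(entries):
        if ":" in entry:
            rank, name = entry.split(":", 1)
            pairs.append((rank.strip(), name.strip()))
        elif pos < len(CANONICAL_RANKS):
            pairs.append((CANONICAL_RANKS[pos], entry))
        else:
            pairs.append((f"level{pos + 1}", entry))
    return tuple(pairs)


def format_lineage(lineage: Iterable[tuple[str, str]]) -> str:
    return ";".join(f"{rank}:{name}" for rank, name in lineage)


# ---------------------------------------------------------------------------
# sample metadata


_META_COLUMNS = [
    "sample_id",
    "host_species",
    "origin",
    "sex",
    "tissue",
    "dataset_kind",
    "n_orfs",
]


def read_sample_meta(path: PathLike) -> list[SampleMeta]:
    """Read per-sample metadata from a headered TSV."""
    path = Path(path)
    if not path.exists():
        raise ParserError(f"no such file: {path}")
    out: list[SampleMeta] = []
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_META_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ParserError(f"metadata table missing columns: {sorted(missing)}")
        for row in reader:
            out.append(
                SampleMeta(
                    sample_id=row["sample_id"],
                    host_species=row["host_species"],
                    origin=row["origin"],
                    sex=row["sex"],
                    tissue=row["tissue"],
                    dataset_kind=row["dataset_kind"],
                    n_orfs=int(row["n_orfs"]),
                )
            )
    return out


def write_sample_meta(samples: Iterable[SampleMeta], path: PathLike) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_META_COLUMNS)
        for s in samples:
            writer.writerow(
                [s.sample_id, s.host_species, s.origin, s.sex, s.tissue,
                 s.dataset_kind, s.n_orfs]
            )
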