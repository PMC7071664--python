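"""Lignocellulose functional classification of CAZyme calls.

A CAZy family is only a container: a single family can hold both
lignocellulose-degrading enzymes and enzymes acting on other substrates
(chitin, pectin, starch, ...). Calls in watchlisted families are therefore
resolved per ORF: an explicit activity prediction from the peptide-signature
predictor takes precedence; calls without one fall back to the family's
most common activity in the CAZy database. Activity strings are matched
against a small controlled vocabulary of case-insensitive synonyms;
unmatched strings yield ``unresolved``, never a guess.

The packaged class map (``data/ligno_class_map.tsv``) seeds the watchlist
of lignocellulose-degrading families — cellulases (endocellulases,
beta-glucosidases, a cellobiose phosphorylase, LPMOs), hemicellulases and
lignin-modifying enzymes (laccases, cellobiose dehydrogenases,
peroxidases). Entries are marked by provenance (named in the study text vs
curated standard members) and scope (microbiota core list, host-specific,
extended), and users may ship an edited copy.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from holocaz.consensus import CazymeCall
from holocaz.model import SampleMeta, cazy_class

ROLES = (
    "cellulase_endo",
    "cellulase_betaglucosidase",
    "cellulase_phosphorylase",
    "cellulase_lpmo",
    "hemicellulase",
    "lme_laccase",
    "lme_cdh",
    "lme_peroxidase",
    "other",
)

#: Classification status of a call.
LIGNOCELLULOLYTIC = "lignocellulolytic"
OTHER_SUBSTRATE = "other_substrate"
UNRESOLVED = "unresolved"
NOT_APPLICABLE = "not_applicable"

# Controlled activity vocabulary: lowercase synonym -> role. Anything not
# listed here is unresolved.
_LIGNO_ACTIVITY_ROLE = {
    "cellulase": "cellulase_endo",
    "endocellulase": "cellulase_endo",
    "endoglucanase": "cellulase_endo",
    "endo-beta-1,4-glucanase": "cellulase_endo",
    "beta-glucosidase": "cellulase_betaglucosidase",
    "cellobiase": "cellulase_betaglucosidase",
    "cellobiose phosphorylase": "cellulase_phosphorylase",
    "lpmo": "cellulase_lpmo",
    "lytic polysaccharide monooxygenase": "cellulase_lpmo",
    "xylanase": "hemicellulase",
    "endo-1,4-beta-xylanase": "hemicellulase",
    "beta-xylosidase": "hemicellulase",
    "alpha-xylosidase": "hemicellulase",
    "arabinoxylanase": "hemicellulase",
    "glucuronoxylanase": "hemicellulase",
    "xylan alpha-glucuronidase": "hemicellulase",
    "alpha-glucuronidase": "hemicellulase",
    "mannanase": "hemicellulase",
    "beta-mannanase": "hemicellulase",
    "beta-mannosidase": "hemicellulase",
    "alpha-mannosidase": "hemicellulase",
    "beta-mannoside phosphorylase": "hemicellulase",
    "xyloglucanase": "hemicellulase",
    "licheninase": "hemicellulase",
    "alpha-arabinofuranosidase": "hemicellulase",
    "arabinofuranosidase": "hemicellulase",
    "endo-beta-1,4-galactanase": "hemicellulase",
    "beta-galactosidase": "hemicellulase",
    "alpha-galactosidase": "hemicellulase",
    "alpha-fucosidase": "hemicellulase",
    "alpha-rhamnosidase": "hemicellulase",
    "acetyl xylan esterase": "hemicellulase",
    "feruloyl esterase": "hemicellulase",
    "glucuronoyl esterase": "hemicellulase",
    "hemicellulase": "hemicellulase",
    "laccase": "lme_laccase",
    "cellobiose dehydrogenase": "lme_cdh",
    "peroxidase": "lme_peroxidase",
    "manganese peroxidase": "lme_peroxidase",
    "lignin peroxidase": "lme_peroxidase",
}

_OTHER_ACTIVITIES = {
    "chitinase",
    "chitosanase",
    "chitin deacetylase",
    "pectinase",
    "pectate lyase",
    "pectin lyase",
    "pectin methylesterase",
    "polygalacturonase",
    "amylase",
    "alpha-amylase",
    "pullulanase",
    "sialidase",
    "trehalase",
    "agarase",
    "lysozyme",
    "invertase",
    "levanase",
    "alpha-glucosidase",
}


@dataclass(frozen=True)
class ActivityPrediction:
    """An enzymatic-activity prediction for one (ORF, family) pair."""

    orf_id: str
    family: str
    predicted_activity: str
    source: str = "peptide_predictor"  # peptide_predictor | family_default


@dataclass(frozen=True)
class ClassMapEntry:
    family: str
    roles: tuple[str, ...]
    lignocellulolytic_default: bool
    most_common_activity: str
    scope: str = "microbiota"  # microbiota | host | both | extended
    provenance: str = "curated"  # text | curated | user


@dataclass
class ClassMap:
    """Watchlist of lignocellulose-degrading CAZy families and their roles."""

    entries: dict[str, ClassMapEntry] = field(default_factory=dict)

    def __contains__(self, family: str) -> bool:
        return family in self.entries

    @property
    def families(self) -> frozenset[str]:
        return frozenset(self.entries)

    def core_microbiota_families(self) -> frozenset[str]:
        """The metagenome watchlist: scope microbiota or both."""
        return frozenset(
            f for f, e in self.entries.items() if e.scope in ("microbiota", "both")
        )

    def validate_covers(self, families: Iterable[str]) -> None:
        missing = sorted(set(families) - set(self.entries))
        if missing:
            raise ValueError(f"class map missing watchlist families: {missing}")


def load_class_map(path: Optional[Union[str, Path]] = None) -> ClassMap:
    """Load the packaged class map, or a user-supplied TSV with the same
    columns (family, roles, lignocellulolytic_default, most_common_activity,
    scope, provenance)."""
    if path is None:
        ref = resources.files("holocaz").joinpath("data/ligno_class_map.tsv")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    entries: dict[str, ClassMapEntry] = {}
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    for row in reader:
        roles = tuple(r.strip() for r in row["roles"].split(",") if r.strip())
        unknown = [r for r in roles if r not in ROLES]
        if unknown:
            raise ValueError(f"unknown roles {unknown} for family {row['family']}")
        if not roles:
            raise ValueError(f"family {row['family']} has no roles")
        entries[row["family"]] = ClassMapEntry(
            family=row["family"],
            roles=roles,
            lignocellulolytic_default=row["lignocellulolytic_default"].lower()
            in ("true", "1", "yes"),
            most_common_activity=row["most_common_activity"],
            scope=row.get("scope", "microbiota") or "microbiota",
            provenance=row.get("provenance", "user") or "user",
        )
    return ClassMap(entries=entries)


@dataclass(frozen=True)
class AnnotatedCall:
    """A CAZyme call with its lignocellulose classification.

    ``status`` is one of lignocellulolytic / other_substrate / unresolved
    for watchlist families, and not_applicable otherwise. ``activity_source``
    records whether the status came from an explicit predictor activity or
    the family's most-common-activity default (never both).
    """

    call: CazymeCall
    status: str
    role: Optional[str] = None
    activity: Optional[str] = None
    activity_source: Optional[str] = None  # peptide_predictor | family_default


def _resolve_activity(activity: str) -> tuple[str, Optional[str]]:
    key = activity.strip().lower()
    if key in _LIGNO_ACTIVITY_ROLE:
        return LIGNOCELLULOLYTIC, _LIGNO_ACTIVITY_ROLE[key]
    if key in _OTHER_ACTIVITIES:
        return OTHER_SUBSTRATE, "other"
    return UNRESOLVED, None


def classify_calls(
    calls: Iterable[CazymeCall],
    activities: Iterable[ActivityPrediction],
    class_map: ClassMap,
) -> list[AnnotatedCall]:
    """Label each call lignocellulolytic / other-substrate / unresolved.

    Precedence is total: a call with an explicit predictor activity for its
    (ORF, family) never falls back to the family default, and vice versa.
    Calls outside the watchlist are labelled not_applicable.
    """
    predicted: dict[tuple[str, str], ActivityPrediction] = {}
    for act in activities:
        if act.source != "peptide_predictor":
            continue
        predicted[(act.orf_id, act.family)] = act
    out: list[AnnotatedCall] = []
    for call in calls:
        if call.family not in class_map:
            out.append(AnnotatedCall(call, NOT_APPLICABLE))
            continue
        pred = predicted.get((call.orf_id, call.family))
        if pred is not None:
            status, role = _resolve_activity(pred.predicted_activity)
            out.append(
                AnnotatedCall(call, status, role, pred.predicted_activity,
                              "peptide_predictor")
            )
        else:
            entry = class_map.entries[call.family]
            status, role = _resolve_activity(entry.most_common_activity)
            if status == UNRESOLVED and entry.lignocellulolytic_default:
                status, role = LIGNOCELLULOLYTIC, entry.roles[0]
            out.append(
                AnnotatedCall(call, status, role, entry.most_common_activity,
                              "family_default")
            )
    return out


@dataclass
class ClassSummary:
    """Module- and family-level breakdown of watchlist calls.

    Percentages are computed over modules with an explicit predictor
    activity that resolved to a substrate class; they are ``None`` (not 0)
    when no module carries a prediction.
    """

    n_watchlist_modules: int
    n_predicted_modules: int
    n_ligno_predicted: int
    n_other_predicted: int
    n_ligno_total: int
    n_other_total: int
    n_unresolved: int
    families_by_class: dict[str, int]

    @property
    def n_families(self) -> int:
        return sum(self.families_by_class.values())

    @property
    def pct_predicted(self) -> Optional[float]:
        if self.n_watchlist_modules == 0:
            return None
        return 100.0 * self.n_predicted_modules / self.n_watchlist_modules

    @property
    def pct_ligno_predicted(self) -> Optional[float]:
        resolved = self.n_ligno_predicted + self.n_other_predicted
        if resolved == 0:
            return None
        return 100.0 * self.n_ligno_predicted / resolved

    @property
    def pct_other_predicted(self) -> Optional[float]:
        resolved = self.n_ligno_predicted + self.n_other_predicted
        if resolved == 0:
            return None
        return 100.0 * self.n_other_predicted / resolved


def summarize_classes(annotated: Iterable[AnnotatedCall]) -> ClassSummary:
    """Summarize watchlist calls: modules per status, families per class.

    Modules are weighted by ``module_count``; family counts are distinct
    watchlist families observed among the calls, tallied per CAZy class.
    """
    annotated = list(annotated)
    watch = [a for a in annotated if a.status != NOT_APPLICABLE]
    n_modules = sum(a.call.module_count for a in watch)
    pred = [a for a in watch if a.activity_source == "peptide_predictor"]
    n_pred = sum(a.call.module_count for a in pred)
    n_ligno_pred = sum(
        a.call.module_count for a in pred if a.status == LIGNOCELLULOLYTIC
    )
    n_other_pred = sum(
        a.call.module_count for a in pred if a.status == OTHER_SUBSTRATE
    )
    n_ligno = sum(a.call.module_count for a in watch if a.status == LIGNOCELLULOLYTIC)
    n_other = sum(a.call.module_count for a in watch if a.status == OTHER_SUBSTRATE)
    n_unres = sum(a.call.module_count for a in watch if a.status == UNRESOLVED)
    fams = sorted({a.call.family for a in watch})
    by_class: dict[str, int] = {}
    for fam in fams:
        by_class[cazy_class(fam)] = by_class.get(cazy_class(fam), 0) + 1
    return ClassSummary(
        n_watchlist_modules=n_modules,
        n_predicted_modules=n_pred,
        n_ligno_predicted=n_ligno_pred,
        n_other_predicted=n_other_pred,
        n_ligno_total=n_ligno,
        n_other_total=n_other,
        n_unresolved=n_unres,
        families_by_class=by_class,
    )


def breakdown_table(
    annotated: Sequence[AnnotatedCall],
    meta: Sequence[SampleMeta],
    by: str = "sample_id",
) -> pd.DataFrame:
    """Per-group module counts by classification status.

    ``by`` is any SampleMeta attribute (sample_id, tissue, host_species,
    origin, sex, dataset_kind).
    """
    meta_by_id = {m.sample_id: m for m in meta}
    rows = []
    for a in annotated:
        if a.status == NOT_APPLICABLE:
            continue
        m = meta_by_id.get(a.call.sample_id)
        group = getattr(m, by) if m is not None else a.call.sample_id
        rows.append({"group": group, "status": a.status, "role": a.role or "",
                     "modules": a.call.module_count})
    if not rows:
        return pd.DataFrame(columns=["group", "status", "role", "modules"])
    df = pd.DataFrame(rows)
    return (
        df.groupby(["group", "status", "role"], as_index=False)["modules"]
        .sum()
        .sort_values(["group", "status", "role"], ignore_index=True)
    )
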