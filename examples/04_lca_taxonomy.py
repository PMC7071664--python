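"""Lowest-common-ancestor taxonomy of CAZyme ORFs and a community profile."""

from holocaz import lca, profile_community
from holocaz.consensus import CazymeCall
from holocaz.domain_io import parse_lineage
from holocaz.model import TaxonLineage, Tool
from holocaz.taxonomy import assign_orfs

ALL = frozenset(Tool)

hits = [
    TaxonLineage("orf_1", 1, parse_lineage(
        "Bacteria;Bacteroidetes;Flavobacteriia;Flavobacteriales")),
    TaxonLineage("orf_1", 2, parse_lineage(
        "Bacteria;Bacteroidetes;Cytophagia;Cytophagales")),
    TaxonLineage("orf_2", 1, parse_lineage(
        "Bacteria;Proteobacteria;Gammaproteobacteria;Vibrionales")),
]

single = lca([h for h in hits if h.orf_id == "orf_1"])
print("orf_1 LCA:", ";".join(n for _, n in single.assigned_lineage))

assignments = assign_orfs(hits)
calls = [CazymeCall("orf_1", "GH43", ALL, 2, "demo"),
         CazymeCall("orf_2", "CE1", ALL, 1, "demo"),
         CazymeCall("orf_3", "AA3", ALL, 1, "demo")]  # no hits -> unknown
profile = profile_community(assignments, calls, level="phylum")
print("\nmodules per phylum and CAZy class:")
print(profile)
print("\norf_1's two Bacteroidetes hits disagree below the phylum, so its")
print("two GH43 modules stop at Bacteroidetes; orf_3 had no database hits")
print("and lands in the 'unknown' row, keeping column sums conserved.")
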