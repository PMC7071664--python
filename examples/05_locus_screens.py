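"""PUL and cellulosome screens on a toy contig set."""

from holocaz import fusion_report, render_pul_map, screen_cellulosome, screen_pul
from holocaz.model import DomainHit, GeneOnContig, Tool


def gene(contig, idx, orf, pfam=(), families=()):
    domains = frozenset(DomainHit(orf, Tool.HMM, a, 1e-12) for a in pfam)
    start = idx * 1000
    return GeneOnContig(contig, idx, start, start + 900, "+", orf,
                        domains, frozenset(families))


genes = [
    # pul_contig: unk - susC - susD - GH43  (a hemicellulose-targeting PUL)
    gene("pul_contig", 1, "p1"),
    gene("pul_contig", 2, "p2", pfam=["PF00593"]),
    gene("pul_contig", 3, "p3", pfam=["PF07980"]),
    gene("pul_contig", 4, "p4", families=["GH43"]),
    # orphan_contig: a lone susC, a fragmented locus
    gene("orphan_contig", 1, "o1", pfam=["PF00593"]),
    # cell_contig: cohesin+SLH scaffoldin and a GH26+CBM35 dockerin fusion
    gene("cell_contig", 1, "c1", pfam=["PF00963", "PF00395"]),
    gene("cell_contig", 2, "c2", pfam=["PF00404"],
         families=["GH26", "CBM35"]),
]

pul = screen_pul(genes)
for cand in pul.candidates:
    print(f"PUL on {cand.contig_id}: {render_pul_map(cand, genes)}")
print(f"orphan-bearing contigs: {pul.orphan_contigs}")

cands = screen_cellulosome(genes)
print("\nenzyme-dockerin fusions (cellulosome evidence):")
print(fusion_report(cands)[["contig_id", "orf_id", "cazymes"]].to_string(index=False))
print("\nOne sequential susC-susD pair makes a PUL candidate; the lone susC")
print("is only tallied. The GH26+CBM35 gene carries a dockerin, the")
print("signature of an enzyme wired into a cellulosome scaffold.")
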