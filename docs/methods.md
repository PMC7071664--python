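# Methods

`holocaz` reconstructs the carbohydrate-active enzyme (CAZyme) repertoire —
the CAZome — of a holobiont from assembled shotgun metagenomes and host
transcriptomes, and screens the assemblies for two bacterial
lignocellulose-degrading systems: polysaccharide utilization loci (PULs)
and cellulosomes. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic validation does and
does not demonstrate.

## Consensus CAZyme calling

Input is per-ORF domain evidence from three independent annotation
streams: a profile-HMM search against a CAZyme domain database, a
sequence-similarity search against annotated CAZyme sequences, and a
conserved short-peptide signature search. A (ORF, family) assignment is
accepted only when all three streams report it — the conservative
intersection rule. Everything with one- or two-tool support is preserved
in a partial-evidence side channel for inspection but never counted.

Counting unit: a "CAZyme" is a functional module (domain), not a gene. The
module count of a call is the number of HMM-stream domain hits of that
family on the ORF, because only the HMM stream has per-domain resolution.
A multi-family ORF (e.g. a GH26 + CBM35 fusion) yields one call per
family.

Agreement is evaluated at family level by default: GH5_13 (HMM) and GH5_4
(similarity) agree at GH5. The streams differ systematically in subfamily
resolution, and family level is where comparative repertoires are
reported; `subfamily=True` switches to exact-label agreement. Agreement is
per ORF, not per overlapping coordinate interval — the streams report
coordinates inconsistently (the peptide stream not at all), so coordinate
overlap would silently bias against the peptide stream.

Tunable gates: similarity hits pass an E-value threshold (default 1e-50,
the stringency used when pre-annotated CAZyme databases are searched with
fast aligners); the peptide stream carries a signature score, not an
E-value, and is unfiltered by default (`peptide_min_score` is exposed).
Under independent per-stream sensitivity q on a true CAZyme, the expected
consensus recall is q³ — the property the synthetic validation measures.

## Quantification

Raw module counts are not comparable across samples of different
sequencing depth. Each count is divided by the sample's total predicted
ORF count (relative abundance) and multiplied by the smallest ORF count in
the sample's normalization group:

    normalized(f, s) = raw(f, s) / n_orfs(s) × min over group(s) of n_orfs

The group's shallowest library therefore keeps its raw counts and deeper
libraries scale down proportionally. Groups default to dataset-kind strata
(metagenomes vs transcriptomes are never placed on a common reference; a
study mixing metagenome cohorts with very different ORF-calling protocols
should keep them in separate groups too) and are user-overridable.
Normalized values stay unrounded internally; only report layers round.
This is a deliberate minimal design — no rarefaction, size factors, or
compositional transforms — because the downstream statements are about
repertoire presence and relative weight, not differential abundance.

## Lignocellulose classification

A watchlist maps CAZy families to lignocellulose roles: endocellulases
(GH5, GH6, GH8, GH9, GH44, GH48, GH74), beta-glucosidases (GH1, GH3,
GH116), a cellobiose phosphorylase (GH94), lytic polysaccharide
monooxygenases (AA10; AA15 in hosts), hemicellulases (GH and CE families),
laccases (AA1), cellobiose dehydrogenases (AA3) and peroxidases (AA2).
The packaged map (`data/ligno_class_map.tsv`) carries 48 families; its
microbiota core — scope `microbiota` or `both` — is 33 GH + 8 CE + 3 AA =
44 families. Families named in the study this package operationalizes are
marked `provenance=text`; the remaining hemicellulase members are curated
standard CAZy hemicellulase families (`provenance=curated`), since the
full watchlist is only partially enumerated in any one source. The map is
a plain TSV and is meant to be edited.

A family is only a container: GH5, GH8, GH1 and GH3 hold both cellulases
and hemicellulases, and GH18-like families hold chitinases. Per-call
resolution therefore uses an explicit activity prediction when one exists
(matched case-insensitively against a controlled synonym vocabulary;
unmatched strings become `unresolved`, never a guess), and otherwise falls
back to the family's most common database activity. The precedence is
total: a call never mixes both sources. Summary percentages (share of
activity-predicted modules that are lignocellulolytic) are computed over
predicted modules only and are reported as undefined — not zero — when no
module carries a prediction.

## Taxonomy

Each CAZyme-encoding ORF keeps its top-k database hits (default k = 5,
E-value ≤ 1e-4, best score first) and is assigned the naive lowest common
ancestor: lineages are walked rank by rank from domain downward and the
assignment stops at the first disagreement. One hit keeps its full
lineage; hits disagreeing at the domain level leave the ORF unassigned.
No minimum-score or top-percent weighting is applied — the rule is the
plain intersection of retained hits; weighting hooks exist as config stubs.
Lineages are aligned by rank name, and a rank missing from some hits is a
wildcard that never breaks the prefix (hits that do name it must agree).
Community profiles tally modules per taxon and CAZy class at a requested
rank; ORFs unresolved at that rank enter an explicit `unknown` row so
column sums conserve total modules — with environmental communities the
unknown fraction is often large and hiding it would distort the profile.

## Locus screens

Both screens run on gene-ordered contigs; gene order is recomputed from
coordinates on entry, so results are invariant to input ordering.

**PULs.** Markers are the TonB-dependent receptor domain (susC, PF00593)
and the SusD-like domain (susD, PF07980). A candidate requires one
*sequential* pair: susC- and susD-bearing genes at adjacent positions
(gene-index difference exactly 1), either order, strand ignored — the
canonical tandem susC-then-susD same-strand arrangement is available as a
strict mode, but metagenomic gene calling is noisy enough that the default
stays permissive. Contigs carrying markers without an adjacent pair are
tallied as orphan-bearing; in fragmented assemblies these vastly outnumber
intact pairs and the tally is part of the result, not noise. Co-localized
CAZymes default to the whole contig (metagenome contigs are short); a
bp-window option exists for long contigs.

**Cellulosomes.** Markers are cohesin (PF00963), dockerin (default
PF00404, the standard Pfam dockerin family; the accession is configurable
because published marker lists sometimes repeat the cohesin accession for
the dockerin) and the S-layer homology anchor (PF00395). Every
marker-bearing contig is a candidate; genes carrying both a dockerin and a
CAZy family are reported as enzyme-dockerin fusions — the strongest single
piece of evidence for an active cellulosome — in a per-gene table with
sample metadata and contig taxon.

## Synthetic data and what it shows

The generator emulates the *statistical* structure of the inputs, not
sequence content: contig gene models (gene counts uniform on 3–8 per
contig, lengths 300–1500 bp, gaps 20–200 bp), three-tool evidence, Pfam
marker hits, top-k lineages and sample metadata, written in exactly the
formats the readers consume, under one `numpy` PCG64 stream keyed by a
single seed (byte-identical reruns).

Defaults define the validation conditions: 5 planted adjacent susC–susD
pairs and 50 orphan/non-adjacent decoy contigs; 6 cellulosome contigs
carrying 30 enzyme-dockerin fusion genes; 300 background CAZyme ORFs with
per-tool agreement q = 0.8 and a 10% wrong-family confusion rate for
non-agreeing tools; activity predictions emitted for 41.8% of planted
CAZymes. Background CAZymes are subject to the agreement model;
planted-locus CAZymes (PUL-co-localized and fusion genes) get
deterministic three-tool evidence so that every manifest locus is
re-derivable from the files by an independent scan — locus recovery is
meant to test the screens' geometry, not to convolve it with annotation
noise (the manifest separates the two populations).

Passing these tests shows the consensus rule has exact intersection
semantics (empirical recall within the binomial 95% interval of q³ at
n = 2000), the screens recover planted geometry exactly, and the whole
pipeline is deterministic. It does **not** show robustness to real HMM
score distributions, chimeric assemblies, fragmented ORFs or database
bias — none of which the generator models.

## Numerical and degenerate-input choices

- Coordinates are 1-based inclusive (GFF convention) everywhere.
- Gene order ties (equal starts) break by end, then ORF id; duplicate ORF
  ids warn and keep both records (strict mode makes them fatal).
- Readers skip malformed rows with line-numbered warnings by default;
  strict mode turns any of them fatal. Skipped rows are counted and
  surfaced in the run manifest.
- Empty inputs yield empty outputs; percentages over empty denominators
  are `None`; precision of an empty prediction set is `None` (reported NA).
- Consensus output is sorted by (ORF, family); no tie-breaking is needed
  anywhere in the consensus because set intersection is order-free.
- The problem sizes used by the validation suite (n = 2000 ORFs for the
  recall check, 120–600 contigs elsewhere) were chosen as the smallest
  sizes at which the binomial interval is meaningfully tight.

## Known limitations

- Per-ORF (not per-coordinate) agreement can merge two distinct same-family
  domains reported by different tools into one call; module counts still
  come from the HMM stream alone.
- The naive LCA is sensitive to a single stray hit (one bad top-5 hit
  collapses the assignment toward root); weighted variants are stubs.
- The watchlist is a curated file, not an inference; families it omits are
  `not_applicable` by construction.
- The orphan tally counts contigs, not orphan domains; a contig with three
  lone susC genes tallies once.
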