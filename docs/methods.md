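# Methods

## Overview

`salimet` re-implements, as a tested library, a saliva metaproteomics
analysis workflow: search-engine protein-group tables are filtered,
taxonomically assigned by lowest common ancestor (LCA), used to build a
reduced second-pass search space, and then profiled quantitatively (kingdom
biomass, genus/species abundance, between-group statistics on human
proteins) and functionally (orthologous-group annotation, KEGG pathway
enrichment). A seedable synthetic-cohort generator with planted ground
truth drives all end-to-end testing.

## Taxonomic assignment

Taxonomy is read from NCBI-dump dialect files (`nodes.dmp`, `names.dmp`,
`merged.dmp`). Lineages retain every node on the root path — including
`no rank`/`clade` nodes — and are never collapsed onto canonical ranks, so
an LCA may carry any rank label; the reported rank is the literal label.
Retired ids resolve transitively through the merged map; ids absent from
both nodes and merged (deleted taxa) raise errors rather than being
silently dropped, which would otherwise bias LCA depth. Name resolution is
exact match, then case-insensitive, then an error carrying the name; no
fuzzy matching, because it is irreproducible.

The LCA of a protein group is the deepest node shared by the lineages of
the taxa its accessions map to. In the first pass only the accessions with
the most peptide associations vote; all tied accessions are kept, so the
result does not depend on input order. In the second pass every accession
votes, which can only move the LCA toward the root (the voting set grows).

**Primate override.** Curated protein databases mix primate orthologs, so a
group whose LCA lands in the parvorder Catarrhini is in practice a human
protein. The default (`ancestor` mode) also re-labels above-species LCAs
inside the Catarrhini clade (genus Homo, family Hominidae, ...) for the
same reason, while a clean species-level assignment to a non-human primate
is left alone. `exact` mode restricts the rule to LCA == Catarrhini; both
behaviours are available because the narrower reading is also defensible.

**Search-space reduction.** Genus- and species-rank LCAs, expanded to all
taxonomic descendants, select the records of the reduced FASTA;
sub-species LCAs are promoted to their species first (they satisfy
"species and its descendants" and are logged). All human records are
included whenever any assignment is human. Record taxa come from a sidecar
accession→taxid table or an `OX=` header token, sidecar winning on
conflict.

## Filters

Two filters are deliberately distinct because their definitions differ:

* identification filter: ≥ 2 unique peptides AND detected (intensity > 0)
  in ≥ 5 of 30 samples — applied before taxonomic assignment;
* quantification filter: razor+unique peptides > 1 AND detected in
  strictly more than 5 samples — applied before normalisation.

"Detected" means intensity strictly greater than zero (MaxQuant-style
tables write 0 for non-detection). Rows flagged reverse or contaminant are
dropped when the flag columns exist; flag-free dialects pass through.

## Quantification and statistics

**Quantile normalisation** follows the limma convention. The reference
distribution is the mean across samples of each sample's observed
quantiles on a common grid; each sample's observed values are mapped onto
it by rank, with tied values receiving the mean of their target quantiles.
Missing cells stay missing. After normalisation all columns with equal
observed counts share identical sorted values.

**Transforms and imputation.** Observed intensities are log2-transformed.
The constant floor 19 (log2 scale, the study's lowest measured intensity)
is imputed *only* on the PCA path, which needs complete data. The ANOVA
screen runs on observed values (proteins with fewer than two observations
in any group are skipped and logged; so are proteins with zero between-
and within-group variance, where F is undefined). The clustering path
imputes at the row mean instead: after row mean-centring a row-mean
imputation is neutral, whereas the constant floor turns sporadically
missing cells into large distance outliers (see Design choices).

**Biomass and abundance.** Kingdom biomass is each kingdom's share of
total summed intensity. Genus/species abundance assigns each bacterial
group's intensity to the rank-level ancestor on its LCA lineage; groups
whose LCA sits above the rank are excluded from both numerator and
denominator, and sample columns are normalised to 1. Raw summed
intensities are used by default (a switch to normalised values exists);
relative abundances are scale-free per sample either way.

**Tests.** Taxon comparisons (caries vs healthy, periodontitis vs healthy)
use the two-sided Mann–Whitney U test: the exact null distribution when
the pooled values are tie-free, otherwise the normal approximation with
tie correction; fully tied data returns p = 1. Benjamini–Hochberg
correction is applied within each comparison across taxa, and across
proteins for the ANOVA screen (the upstream study does not name its
multiple-testing method for the ANOVA; BH keeps the package internally
consistent, and counts of significant proteins may therefore differ from
a permutation-FDR analysis of the same data). PCA components are ordered
by explained variance with the sign fixed so the largest-magnitude
loading is positive. Hierarchical clustering row-mean-centres the
ANOVA-significant proteins, uses Euclidean distances and Ward linkage,
and is deterministic for a fixed input order.

## Functional annotation and enrichment

HMM hits against bacterial orthologous-group (NOG) models are kept when
E ≤ 1e-4 and accepted greedily in ascending E-value (ties broken by
coordinates then model id), rejecting hits that overlap an accepted
envelope by more than 8 residues (inclusive coordinates:
`min(end) − max(start) + 1`). Accepted NOGs map to GO terms and KEGG
pathways; a protein's terms are the union over its accepted NOGs.

Enrichment between two sample categories uses Fisher's exact test on the
2×2 term-vs-rest association table per KEGG term (association counts are
protein-group–term pairs; a group detected in a category contributes one
association per term). Only bacterial groups with an LCA at genus rank or
below participate. BH correction runs across terms; a term is significant
when q ≤ 0.01 AND its share fold change is ≥ 2 or ≤ 0.5. A +0.5 count
correction is applied to both groups' shares when either count is zero.
The per-category functional overview ranks pathways by association
percentage (ties by term id) and keeps the minimal prefix reaching 90%
cumulative coverage.

## Synthetic cohorts

The generator emulates the study design: three groups
(periodontitis/caries/healthy) of 10 samples; 2,000 human, 1,900
bacterial and 100 food/other protein groups; kingdom biomass targets
95/3/2%. Its fixture taxonomy (73 nodes) holds both superkingdoms, the
Catarrhini parvorder with human and macaque, ten oral bacterial genera
with 22 species and three strains, and food taxa, and round-trips through
the dump parser.

Key modelling choices, with defaults:

* **Intensities**: per-protein log2 baselines ~ Normal(μ_kingdom, 1.5),
  with μ per kingdom set so expected summed intensities hit the biomass
  targets (bacterial baseline μ = 22; values span roughly 19–30, matching
  the floor constant 19); per-sample noise sd 0.8 log2 units.
* **Genus profile**: Streptococcus 0.22, Prevotella 0.14, Veillonella
  0.12, Rothia 0.11, Neisseria 0.11 (the five predominant genera, 70% of
  bacterial mass), Haemophilus/Fusobacterium/Leptotrichia 0.10 each.
  Planted disease effects: Veillonella ×3 in caries, Fusobacterium ×3 in
  periodontitis, Haemophilus ×1/3 in both. A per-(sample, genus) wobble
  (sd 0.3 log2) shared across a genus's proteins provides biological
  overdispersion.
* **Differential human proteins**: 60 planted, 2.0 log2 units (4-fold, the
  size typical of salivary inflammation markers), in three response
  patterns (up in both diseases / caries-specific /
  periodontitis-specific). Planted proteins are co-regulated through one
  inflammation-severity score per sample (disease samples centred at 1,
  sd 0.3; healthy baseline inflammation centred at 0, sd 0.15), and every
  human protein carries a small severity loading (sd 0.3 log2) —
  oral inflammation shifts saliva composition broadly, e.g. through serum
  leakage. Without this co-regulation a 60-protein signature stays below
  the noise floor of a 2,000-feature PCA regardless of effect size, which
  no real inflammation signature does.
* **LCA structure**: bacterial accession sets are drawn to land 2% of
  LCAs at strain, 32% at species, 58% at genus and 8% at family level
  (cross-genus pairs within Streptococcaceae/Veillonellaceae), matching
  the ~92% genus-mapped / ~34% species-mapped bookkeeping of the study;
  2% of human groups carry a macaque ortholog accession (tied peptide
  counts) to exercise the Catarrhini rule.
* **Missingness**: intensity-dependent (rate 0.10 on average; low
  abundance more likely missing), the situation the constant-floor
  imputation is designed for.
* **Peptide counts**: per-accession Poisson with rate proportional to the
  log-intensity, min 1, so majority-accession selection sees realistic
  ties.

What the generator does **not** emulate: peptide-level evidence, spectra
or search-engine scoring; database redundancy (each accession maps to one
taxon); shared peptides across groups; batch effects. Passing recovery
tests therefore show the pipeline's operations are correct and calibrated
under the planted model — not that the study's raw-data-dependent counts
(35,664 peptides, 4,161 proteins, 17.9% PC1 variance, 60 ANOVA hits,
135→50 KEGG terms) are reproducible; those require the deposited raw data
and the 2014 database versions.

## Problem sizes and determinism

Recovery and calibration runs use the full 3×10 cohort design: 20 seeds
for biomass/recall/cluster recovery, 100 seeded runs for the single
planted genus shift, 1,000 proteins for the ANOVA null, 50×200 terms for
the enrichment null, and 50 trees × 100 taxon sets for the LCA oracle.
All randomness flows from numpy Generators seeded per run; identical
seeds give byte-identical generator output (intensities are serialised at
fixed precision).

## Known limitations

* The second identification pass is external: the pipeline emits the
  reduced FASTA and consumes whatever protein-group table the search
  engine produces against it; in tests the generator re-emits its groups
  restricted to the reduced accession set.
* Contaminant handling follows a documented default (drop flagged rows);
  the upstream study does not state its own.
* The overview-table species-level percentages printed for two of the
  study's sample-group columns are inconsistent with their own printed
  counts; the report generator always recomputes percentages from counts.
* Mann–Whitney switches to the tie-corrected normal approximation as soon
  as any tie is present; with n = 10 + 10 this is standard but slightly
  conservative relative to an exact conditional test.
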