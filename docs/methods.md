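# Methods

`metasort` implements the identification-and-comparison half of a COI
metabarcoding workflow for freshwater macroinvertebrate monitoring samples
that were pre-sorted into six coarse taxonomic groups — Annelida (ANNE),
Crustacea (CRUS), Heteroptera + Coleoptera (HECO), Mollusca (MOLL),
Trichoptera + Odonata + Ephemeroptera (TOE) and a rest group of mostly
Diptera (REST) — and sequenced both separately and as an equal-volume pool
per location. This note records the models, parameter choices and numerical
conventions; empirical numbers quoted here are the ones the test suite and
`scripts/acceptance.py` themselves compute.

## MOTU table processing

Upstream read merging and primer trimming are out of scope; processing
starts either from merged reads (FASTA) or from a MOTU-by-replicate count
table.

**Sequence QC.** Reads pass an inclusive length window of 313–319 bp
(a 316 bp COI fragment ± 3 bp for coding-length variation and primer
slippage), are dereplicated exactly with a minimum abundance of 2, and are
clustered at 98% identity by abundance-ordered greedy centroid clustering:
each sequence joins the first centroid at or above the identity threshold,
else founds a new centroid. Pairwise identity is `1 − d / max(|a|, |b|)`
with `d` the unit-cost global edit distance (edlib). Dividing by the longer
length — the minimum possible alignment span — makes the value independent
of which co-optimal traceback an aligner returns; for substitution-only
differences it equals matching columns over alignment columns (10
mismatches on 316 bp → 306/316 ≈ 96.8%). This clusterer is a desk-scale
stand-in that applies the same decision rule as abundance-sorted centroid
tools without their heuristics and indexing; it is not intended for
million-read libraries.

**Contamination threshold.** PCR plates carry artificial internal control
(AIC) wells. Two signals quantify cross-contamination: AIC reads appearing
in regular replicates, and non-AIC reads appearing in control replicates.
The filtering threshold is the smallest per-replicate relative abundance t
such that zeroing every MOTU with share ≤ t (against the replicate total
*before* filtering, since the contamination proportions are observed on raw
totals) removes both signals — i.e. the maximum offending share, 0 with no
contamination. Under the generator's defaults this lands near the 0.025%
used as the fixed default elsewhere (`FilterConfig`).

**Replicate handling.** After the threshold filter, replicates with strictly
fewer than 4,000 reads are discarded; surviving replicates of a sample are
combined additively (counts summed, MOTUs kept regardless of how many
replicates they occurred in — the permissive strategy that maximises taxon
recovery). Samples with no surviving replicate enter a failed-sample
registry that propagates to the comparison stage.

**Boundary conventions** (used consistently everywhere): share "above"
the threshold = strict `>`; "fewer than 4,000" = strict `<`; the length
window is inclusive at both ends; direct hits need identity strictly `> 98`;
LCA candidates need bit-score strictly `> 170` and identity/coverage `≥ 80`.

**Rarefaction** draws without replacement (multivariate hypergeometric, one
spawned generator per sample so column order is irrelevant). Pools are
rarefied to 15,000 reads and sorted samples to 2,500 — pools combine about
six sorted extracts, so this equalises effective depth. Samples below their
target are kept unrarefied and reported rather than silently dropped.

## Taxonomic assignment

Each MOTU carries up to 100 hits against each of two references: a curated
national (WFD) barcode database and a broad public database used only for
screening. Hits are BLAST-outfmt-6-like rows with a slash-delimited
order/family/genus/species lineage.

**Screening.** A MOTU is discarded as non-target when its best public-database
hit outscores (bit-score) its best curated hit and that hit's order is not
among the register's orders — catching human, *Wolbachia* and similar
contamination as well as mislabelled reference records. The target set is
defined by the register, never hard-coded.

**Direct path.** Hits with identity > 98% at 100% coverage are accumulated
by taxon name and resolved by an ordered rule set: (1) names that do not
resolve to register members are dropped; (2) synonyms map to canonical
names; (3) trinomials collapse to the binomial; (4) species-level names
suppress a genus-level name of the same genus; (5) a curated blocklist
removes known bad reference records (an explicit, versioned stand-in for
expert judgement; empty by default); (6) if one species' best identity beats
every competitor's by at least `consistency_margin` (default 0.5 percentage
points) it is kept alone; (7) any remaining tie is kept whole as a species
complex. Complexes are reported in full but contribute their genus-level
ancestor to aggregated taxon lists so that downstream set operations stay
single-valued.

**LCA path.** Without an accepted direct result, candidates are hits with
identity ≥ 80%, coverage ≥ 80% and bit-score > 170, restricted to bit-scores
within 5% of the best candidate (a top-percent filter on score, not "the
best five hits" — the convention of score-window LCA classifiers). The
lowest common ancestor of the candidate lineages is reported, capped at
genus: a single-species candidate set yields its genus, never the species.
Results shallower than order are discarded.

Aggregation sums reads per final taxon per sample, which collapses
haplotype-split conspecific MOTUs and low-abundance pseudogene MOTUs that
resolved to the same name; sample lists are then unioned to location level,
with pooled samples kept separate.

## Morphology-vs-DNA comparison

Both lists are first canonicalised against the register and
redundancy-removed: an entry whose taxon is a strict ancestor of another
entry at the same location is dropped (generalised along the whole lineage —
family entries give way to contained genera exactly as genus entries give
way to contained species; the rationale is that the higher-rank record is
either an uncertainty or a duplicate). The narrow genus-vs-species-only
variant remains available (`remove_redundant(..., ranks_above="genus")`).

Taxa from failed samples are removed from the morphology list before the
sorted-route comparison (they could only ever count as "not found by DNA");
a failed pool removes its location from the pooled comparison.

Every remaining occurrence is classified deterministically, in priority
order, into: (1) found (exact match, consumed pairwise); (2) identified at
a different level (ancestor/descendant pair across the lists); (3) putative
misidentification (different congeneric species on the two lists, paired
alphabetically on ties, leftovers cascading onward); (4) missing in
reference (morphology species absent from the reference database); (5) not
found (covered but morphology-only); (6) extra (DNA-only). Categories 1–3
count as overlap; category 4 counts towards the morphology-only fraction.
The three fractions sum to 1 per location and are averaged unweighted
across locations (matching "on average (range …)" style reporting).
Richness statistics report the Pearson correlation plus both the ratio of
means and the mean of per-location ratios, since summary prose rarely says
which basis it used. Significance testing (e.g. Dunn's test) is deliberately
not included; the per-location values are exported for external statistics.
A location × taxon presence/absence matrix is exported for external
ecological-quality-ratio software; EQR formulas themselves are out of scope.

## Synthetic study generator

The generator emulates a 25-location survey with the six groups above, two
PCR replicates per sample, and both routes (sorted, pooled) from identical
underlying communities, with full ground truth for every read.

Per-group species pools (60/40/60/45/70/90) nest in genera of ~2.2 species
(geometric), three genera per family, three families per order, with 8%
synonyms and occasional non-register congeners present only in the
reference database. Reference coverage is 63.5% for ANNE, 96.5% for TOE and
86% elsewhere. Mean per-sample richness is (6, 6, 8, 7, 8, 12) by group,
~47 taxa per location.

Read counts are multinomial draws at lognormal replicate depths (mean
≈ 28,300 reads, min 4,000 for non-failed replicates) over weights
`biomass × species amplification factor`, both lognormal (σ = 1.5 each).
Species whose weights the primers essentially miss (dropout rate 0.12,
factor 10⁻³) model hard primer bias: they fail on both routes, feeding the
"not found" category. In pools, each group's weight is additionally
multiplied by a heavy-tailed per-(location, group) amplification factor
(lognormal, σ = 2.5): the resulting single-group and single-taxon read
dominance is the mechanism by which pooling loses taxa while sorting does
not. Species split into 1–3 haplotype MOTUs (geometric, mean ≈ 1.5), and
15% carry a pseudogene MOTU at 3% of the parent's reads that only resolves
to genus. Whole-sample amplification failures use the observed per-group
frequencies (MOLL 0.54, ANNE 0.16, HECO 0.12, CRUS 0.04, TOE 0.04, REST 0;
pools 0.04). AIC contamination hits 15% of non-failed regular replicates at
up to 2.5 × 10⁻⁴ relative abundance (failed PCRs amplify nothing, spike-in
included); controls receive foreign reads at half that rate. Morphological
lists carry congeneric misidentification swaps (6%), genus-level-only
records (8%) and overlooked taxa (10%, the source of DNA-only extras).

Hit-table identities are drawn from fixed bands per situation (covered
species 98.6–100%, congeners 85–93%, pseudogenes 88–95%) with a monotone
identity→bit-score map for a ~316 bp amplicon, rather than from simulated
sequences; `simulate_reads` provides substitution-only sequence simulation
separately to exercise the clustering kernel. The skew parameters were
chosen so that the generator reproduces the qualitative structure of real
sorted-vs-pooled surveys — pools frequently dominated by one group and
sometimes one taxon, sorted recovery strictly above pooled, pooled
comparisons dominated by morphology-only taxa — and then frozen.

What the generator does *not* emulate: realistic COI sequence evolution,
chimeras, quality scores, tag jumps beyond the uniform AIC model, and
correlated community structure across locations. Passing tests therefore
demonstrate that the pipeline's logic is correct under the stated
statistical structure, not that real libraries meet that structure.

## Numerical and reproducibility choices

All randomness flows from a single integer seed through
`numpy.random.default_rng`; fixed seed ⇒ bit-identical outputs (asserted in
tests, including CLI reruns). Deterministic tie-breaks throughout:
dereplication orders by abundance then first occurrence; classification
pairs alphabetically; candidate scans take the first qualifying match.
Degenerate inputs are explicit errors (empty LCA input, rarefaction beyond
total depth, fractions of an empty entry set, fewer than three pairs for a
correlation, missing control replicates) rather than silent defaults;
unmatched names are flagged and carried, never dropped.

Problem sizes in the default test and acceptance runs — 25 locations, ~600
MOTUs, ~350 replicates, 20 replicate studies for the sorted-vs-pooled
property — keep a full run to a few seconds on one core while leaving every
mechanism (failures, contamination, coverage gaps, dominance) represented
at realistic rates.

## Known limitations

The greedy clusterer is quadratic in the number of unique sequences; real
libraries should be clustered upstream. Rule 6 reduces "matched
consistently higher" to a best-identity margin, which is cruder than expert
review of full hit tables. Species complexes lose species-level resolution
in aggregated lists by design. The comparison's alphabetical congener
pairing can differ from a manual pairing when a genus has three or more
unmatched species across the lists; leftovers then cascade to categories
4–6, which is why swap recall on synthetic truth is asserted at a 0.85
detection bound rather than 1.
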