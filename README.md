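# metasort

Metabarcoding MOTU filtering, LCA-based taxonomic assignment and
morphology-vs-DNA taxon-list comparison for taxonomically sorted
macroinvertebrate bulk samples.

## The problem

Water-quality monitoring (e.g. under the EU Water Framework Directive)
builds taxon lists for freshwater macroinvertebrate bulk samples, classically
by morphological identification. DNA metabarcoding of a COI fragment can
replace or supplement that, but complex bulk samples suffer from uneven
biomass, preferential amplification (one taxon or group can swallow most of
the reads in a pooled extract), incomplete reference databases, haplotype
and pseudogene inflation of MOTU counts, and cross-sample contamination.
Pre-sorting samples into six coarse groups — Annelida (ANNE), Crustacea
(CRUS), Heteroptera+Coleoptera (HECO), Mollusca (MOLL),
Trichoptera+Odonata+Ephemeroptera (TOE), and the rest, mostly Diptera
(REST) — before extraction and amplification mitigates the dominance
problem at minimal taxonomic effort.

`metasort` is for researchers evaluating that design. It provides, as a
tested library plus CLI:

- **MOTU pipeline** — amplicon length window (313–319 bp), exact
  dereplication (min abundance 2), greedy 98% centroid clustering, a
  cross-contamination threshold derived from artificial internal control
  (AIC) spike-ins (smallest relative abundance t whose removal clears all
  AIC reads from samples and all foreign reads from controls), per-replicate
  abundance filtering, discard of replicates under 4,000 reads, additive
  replicate combination, and rarefaction (hypergeometric).
- **Assignment** — per MOTU, from dual BLAST-style hit tables: direct hits
  (identity > 98%, coverage 100%) resolved through an ordered seven-rule
  name-resolution engine (register membership, synonyms, subspecies,
  genus-vs-species, blocklist, best-identity margin, species complexes);
  otherwise a lowest-common-ancestor vote over top-percent candidate hits
  (identity ≥ 80, coverage ≥ 80, bit-score > 170, within 5% of the best
  bit-score), capped at genus; plus a public-database screen that discards
  MOTUs whose best hit is an out-of-register order (human, *Wolbachia*, …).
- **Comparison** — redundancy removal along lineages, failed-sample
  exclusion, six-category classification of every taxon on the combined
  morphology ∪ DNA lists (found / different level / putative
  misidentification / missing in reference / not found / extra), overlap
  fractions, per-group summaries, richness correlation and ratios, and a
  presence/absence export for external water-quality index software.
- **Synthetic study generator** — a fully ground-truthed simulator of a
  25-location sorted + pooled survey (biomass skew, group-level preferential
  amplification, haplotypes, pseudogenes, reference gaps, AIC
  contamination, sample failures, morphological misidentifications) used
  throughout the test suite. See `docs/methods.md` for the model.

## Worked example

```python
import metasort as ms

study = ms.simulate_study(ms.SimConfig(seed=7))        # inputs + ground truth
res = ms.run_pipeline(study.table, study.wfd_hits, study.genbank_hits,
                      study.register, study.morphology, study.refdb_species)

print(f"threshold      {res.threshold:.6f}")
print(f"retained MOTUs {res.retained_motus}")
s, p = res.summary_sorted.overall, res.summary_pooled.overall
print(f"sorted: overlap {s['overlap']:.1%}  morph-only {s['morph_only']:.1%}"
      f"  dna-only {s['dna_only']:.1%}")
print(f"pooled: overlap {p['overlap']:.1%}  morph-only {p['morph_only']:.1%}"
      f"  dna-only {p['dna_only']:.1%}")
rs, rp = res.richness_sorted, res.richness_pooled
print(f"richness: morphology {rs['morph_mean']:.1f}, "
      f"DNA sorted {rs['dna_mean']:.1f}, DNA pooled {rp['dna_mean']:.1f}")
print(f"sorted vs pooled gain {ms.percent_gain(rs['dna_mean'], rp['dna_mean']):.1f}%")
ev = ms.truth_evaluate(study, res)
print(f"species recovery: sorted {ev['recovery_sorted']:.1%}, "
      f"pooled {ev['recovery_pooled']:.1%}; "
      f"false species: {len(ev['false_taxa_sorted'])}")
```

prints

```
threshold      0.000259
retained MOTUs 504
sorted: overlap 79.2%  morph-only 13.2%  dna-only 7.6%
pooled: overlap 56.6%  morph-only 37.9%  dna-only 5.5%
richness: morphology 36.0, DNA sorted 34.0, DNA pooled 27.5
sorted vs pooled gain 23.6%
species recovery: sorted 98.6%, pooled 69.5%; false species: 0
```

Reading this: the derived contamination threshold (0.026% of a replicate's
reads) is at the spike-in scale; after filtering, 504 MOTUs carry reads in
real samples. The sorted route's taxon lists overlap the morphological
lists far more than the pooled route's, whose communities are eaten by
group- and taxon-level read dominance (69.5% of recoverable species found
vs 98.6% when sorted) — while the pipeline invents no species that are not
truly present. The same run is available from the shell:

```bash
metasort all --seed 7 --out run/      # simulates, runs, writes reports
```

which writes assignment reports, per-location and per-group comparison
summaries, taxon lists and presence/absence matrices under `run/`.

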