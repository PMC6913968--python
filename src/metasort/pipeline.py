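"""End-to-end orchestration: MOTU filtering -> assignment -> comparison.

`run_pipeline` ties the stage functions together in the fixed order the
analysis prescribes (contamination-threshold filter, low-depth replicate
discard, additive replicate combination, per-MOTU assignment, aggregation to
location-level taxon lists, redundancy removal, failed-sample exclusion,
six-category classification, summaries) and returns every intermediate
artifact in one result object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import assignment as asg
from . import comparison as cmp
from . import motu as mt
from . import taxonomy as tax


@dataclass
class PipelineResult:
    """All artifacts of one run."""

    threshold: float
    combined: mt.MotuTable
    failed: pd.DataFrame                       # failed-sample registry
    assignments: list[asg.AssignmentResult]
    aggregated: pd.DataFrame                   # sample-level taxon counts
    dna_sorted: tax.TaxonList                  # redundancy-removed
    dna_pooled: tax.TaxonList
    morphology: tax.TaxonList                  # register-matched, redundancy-removed
    morphology_excluded: tax.TaxonList         # additionally failed-samples removed
    entries_sorted: pd.DataFrame               # six-category comparison entries
    entries_pooled: pd.DataFrame
    summary_sorted: cmp.ComparisonSummary
    summary_pooled: cmp.ComparisonSummary
    richness_sorted: dict
    richness_pooled: dict
    removed_redundant: dict[str, pd.DataFrame] = field(default_factory=dict)

    @property
    def retained_motus(self) -> int:
        """MOTUs with reads left in non-control samples after filtering."""
        reps = self.combined.replicates
        cols = [c for c in self.combined.counts.columns
                if not bool(reps.loc[c, "is_control"])]
        return int((self.combined.counts[cols].sum(axis=1) > 0).sum())


def run_pipeline(table: mt.MotuTable, wfd_hits: pd.DataFrame,
                 genbank_hits: pd.DataFrame, register: tax.Register,
                 morphology: tax.TaxonList, refdb_species: frozenset[str],
                 filter_cfg: mt.FilterConfig = mt.FilterConfig(),
                 assign_cfg: asg.AssignConfig = asg.AssignConfig(),
                 resolution_cfg: asg.ResolutionConfig = asg.ResolutionConfig(),
                 threshold: Optional[float] = None) -> PipelineResult:
    """Run the full analysis on one study's inputs.

    ``threshold=None`` derives the MOTU abundance cutoff from the internal
    control; pass a number (e.g. 0.00025) to fix it.
    """
    combined, failed, threshold = mt.run_filtering(table, filter_cfg,
                                                   threshold=threshold)
    active = combined.drop_empty_motus()
    results, agg = asg.assign_all(wfd_hits, genbank_hits, active.counts,
                                  active.replicates, register,
                                  assign_cfg, resolution_cfg)

    dna_sorted = asg.aggregate_to_locations(agg, "dna_sorted", pooled=False)
    dna_pooled = asg.aggregate_to_locations(agg, "dna_pooled", pooled=True)

    morph = morphology.match_to_register(register)
    removed: dict[str, pd.DataFrame] = {}
    morph, removed["morphology"] = tax.remove_redundant(morph, register)
    dna_sorted, removed["dna_sorted"] = tax.remove_redundant(dna_sorted,
                                                             register)
    dna_pooled, removed["dna_pooled"] = tax.remove_redundant(dna_pooled,
                                                             register)

    failed_sorted = {(r.location, r.group) for r in failed.itertuples()
                     if not r.is_control and r.group != "POOL"}
    morph_excl, _ = cmp.exclude_failed(morph, failed_sorted)

    entries_sorted = cmp.classify(morph_excl, dna_sorted, refdb_species,
                                  register)
    # a fully failed pool removes its location from the pooled comparison
    failed_pool_locs = {r.location for r in failed.itertuples()
                        if r.group == "POOL"}
    morph_pool = tax.TaxonList(
        morph.entries[~morph.entries["location"].isin(failed_pool_locs)]
        .reset_index(drop=True), origin=morph.origin)
    entries_pooled = cmp.classify(morph_pool, dna_pooled, refdb_species,
                                  register)

    summary_sorted = cmp.summarize(entries_sorted)
    summary_pooled = cmp.summarize(entries_pooled)

    richness_sorted = _paired_richness(morph_excl, dna_sorted)
    richness_pooled = _paired_richness(morph_pool, dna_pooled)

    return PipelineResult(
        threshold=threshold, combined=combined, failed=failed,
        assignments=results, aggregated=agg, dna_sorted=dna_sorted,
        dna_pooled=dna_pooled, morphology=morph,
        morphology_excluded=morph_excl, entries_sorted=entries_sorted,
        entries_pooled=entries_pooled, summary_sorted=summary_sorted,
        summary_pooled=summary_pooled, richness_sorted=richness_sorted,
        richness_pooled=richness_pooled, removed_redundant=removed)


def _paired_richness(morph: tax.TaxonList, dna: tax.TaxonList) -> dict:
    try:
        return cmp.richness_stats(cmp.richness(morph), cmp.richness(dna))
    except cmp.ComparisonError:
        return {}


def rarefied_richness(result: PipelineResult, register: tax.Register,
                      pooled_depth: int = 15000, sorted_depth: int = 2500,
                      seed: int = 0) -> dict:
    """Re-aggregate the existing assignments on a rarefied count table.

    Pools are rarefied to ``pooled_depth`` reads, each sorted sample to
    ``sorted_depth`` (pools combine about six sorted extracts, hence the
    one-sixth depth). Samples below their target depth are left unrarefied
    and reported. Returns mean MOTU and taxon richness for sorted samples
    (summed per location) and pools, plus their ratios.
    """
    reps = result.combined.replicates
    depths = {s: (pooled_depth if reps.loc[s, "group"] == "POOL"
                  else sorted_depth)
              for s in result.combined.counts.columns
              if not bool(reps.loc[s, "is_control"])}
    rare, skipped = mt.rarefy_table(result.combined, depths, seed=seed)
    agg = asg.aggregate_assignments(result.assignments, rare.counts, reps)

    out: dict = {"skipped": skipped}
    for label, pooled in (("sorted", False), ("pooled", True)):
        lst = asg.aggregate_to_locations(agg, f"dna_{label}", pooled=pooled)
        lst, _ = tax.remove_redundant(lst, register)
        taxa = cmp.richness(lst)
        sel = rare.counts.loc[:, [s for s in depths
                                  if (reps.loc[s, "group"] == "POOL") == pooled]]
        motus_per_loc = {}
        for s in sel.columns:
            loc = reps.loc[s, "location"]
            present = set(sel.index[sel[s] > 0])
            motus_per_loc.setdefault(loc, set()).update(present)
        out[f"{label}_taxon_mean"] = float(taxa.mean()) if len(taxa) else 0.0
        out[f"{label}_motu_mean"] = (
            float(pd.Series({k: len(v) for k, v in motus_per_loc.items()})
                  .mean()) if motus_per_loc else 0.0)
    if out["pooled_taxon_mean"] > 0:
        out["taxon_ratio"] = out["sorted_taxon_mean"] / out["pooled_taxon_mean"]
    if out["pooled_motu_mean"] > 0:
        out["motu_ratio"] = out["sorted_motu_mean"] / out["pooled_motu_mean"]
    return out
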