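"""Per-MOTU taxonomic assignment from dual reference-database hit tables.

Each MOTU carries up to two BLAST-style hit lists: one against a curated
national (WFD) barcode reference and one against a broad public (GenBank
style) reference used to screen out non-target sequences such as human or
*Wolbachia* contamination. Assignment follows two mutually exclusive paths:

* **direct** — hits above 98% identity at full query coverage are accumulated
  by taxon name and resolved through an ordered rule set (register
  membership, synonymy, subspecies collapse, genus-vs-species preference, a
  curated blocklist, a best-identity margin, species complexes);
* **LCA** — without an accepted direct result, candidate hits (identity and
  coverage at least 80%, bit-score above 170, bit-score within 5% of the best
  candidate, MEGAN-style top-percent) vote through a lowest-common-ancestor
  capped at genus.

MOTUs whose final assignment is shallower than order are discarded, as are
MOTUs whose public-database best hit outscores the curated one and falls
outside the register's orders.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .taxonomy import (RANKS, RANK_DEPTH, Register, TaxonList, TaxonRef,
                       lowest_common_ancestor)

HIT_COLUMNS = ("qseqid", "sseqid", "pident", "qcovs", "bitscore", "lineage")


class AssignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AssignConfig:
    """Hit-acceptance thresholds.

    Direct hits require identity strictly above ``direct_min_identity`` (%)
    at exactly ``direct_coverage`` (%) query coverage. LCA candidates need
    identity and coverage at or above their minima, bit-score strictly above
    ``lca_min_bitscore``, and bit-score within ``lca_top_fraction`` of the
    best candidate. LCA calls are capped at ``lca_rank_cap`` and anything
    shallower than ``min_accept_rank`` is discarded.
    """

    direct_min_identity: float = 98.0
    direct_coverage: float = 100.0
    lca_top_fraction: float = 0.05
    lca_min_bitscore: float = 170.0
    lca_min_identity: float = 80.0
    lca_min_coverage: float = 80.0
    lca_rank_cap: str = "genus"
    min_accept_rank: str = "order"

    def __post_init__(self) -> None:
        if not 0 < self.lca_top_fraction < 1:
            raise AssignmentError("lca_top_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ResolutionConfig:
    """Knobs for the direct-hit name-resolution rules.

    ``blocklist`` replaces expert judgement on putative misidentifications or
    contaminated reference records (rule 5) with an explicit, versioned name
    set; empty by default. ``consistency_margin`` operationalises "matched
    consistently higher" (rule 6): one species is kept alone when its best
    identity exceeds every competitor's best identity by at least this many
    percentage points.
    """

    blocklist: frozenset[str] = frozenset()
    consistency_margin: float = 0.5

    def __post_init__(self) -> None:
        if self.consistency_margin < 0:
            raise AssignmentError("consistency_margin must be >= 0")


@dataclass
class AssignmentResult:
    """Final call for one MOTU, with the applied-rule trail."""

    motu: str
    taxa: tuple[TaxonRef, ...]      # empty when discarded/unidentified
    method: str                     # "direct" | "lca" | "discarded"
    rules: tuple[int, ...] = ()
    reads: int = 0
    reason: Optional[str] = None    # populated for discarded MOTUs

    @property
    def taxon(self) -> Optional[TaxonRef]:
        """Single representative taxon: the sole name, or for an unresolved
        species complex the lowest common ancestor of its members."""
        if not self.taxa:
            return None
        if len(self.taxa) == 1:
            return self.taxa[0]
        return lowest_common_ancestor(self.taxa, max_rank="genus")


def load_hits(path, db: Optional[str] = None) -> pd.DataFrame:
    """Read a BLAST-outfmt-6-like TSV with a slash-delimited lineage column
    (order/family/genus/species, truncated at the hit's rank)."""
    df = pd.read_csv(path, sep="\t", dtype={"qseqid": str, "sseqid": str,
                                            "lineage": str})
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise AssignmentError(f"hit table missing columns {sorted(missing)}")
    if db is not None:
        df = df.assign(db=db)
    return df


def hit_taxon(lineage: str, register: Register) -> TaxonRef:
    """TaxonRef for a hit's lineage string; resolved via the register when
    possible so register membership is carried along."""
    parts = tuple(p for p in lineage.split("/") if p)
    if not parts:
        raise AssignmentError("empty hit lineage")
    name = parts[-1]
    ref = register.get(name)
    if ref is not None:
        return ref
    return TaxonRef(name=name, rank=RANKS[len(parts) - 1], lineage=parts,
                    in_register=False)


def find_direct_hits(hits: pd.DataFrame,
                     cfg: AssignConfig = AssignConfig()) -> list[str]:
    """Distinct taxon names with identity strictly above the direct threshold
    at full coverage, in order of appearance."""
    if hits.empty:
        return []
    mask = (hits["pident"] > cfg.direct_min_identity) & \
           (hits["qcovs"] >= cfg.direct_coverage)
    names = [str(l).split("/")[-1] for l in hits.loc[mask, "lineage"]]
    return list(dict.fromkeys(names))


def resolve_direct(names: Sequence[str], hits: pd.DataFrame,
                   register: Register,
                   res: ResolutionConfig = ResolutionConfig()
                   ) -> tuple[list[TaxonRef], list[int]]:
    """Apply the ordered name-resolution rules to accumulated direct-hit names.

    1. non-register species are removed;
    2. synonyms are resolved to canonical names;
    3. subspecies identifications collapse to species;
    4. with both genus-level and species-level names of one genus, the
       species-level names are retained;
    5. blocklisted names (curated putative misidentifications or contaminated
       reference records) are removed;
    6. when one species' best identity beats every other's by at least the
       consistency margin, only it is kept;
    7. otherwise all remaining names are retained (an unresolved complex).

    Returns the surviving taxa and the rule ids that changed the candidate
    set. An empty result means every name was eliminated; the caller then
    falls through to the LCA path.
    """
    applied: list[int] = []
    resolved: list[TaxonRef] = []
    dropped_nonregister = False
    via_synonym = False
    via_subspecies = False
    for raw in names:
        m = register.match_name(raw)
        if not m.matched or not m.taxon.in_register:
            dropped_nonregister = True          # rule 1
            continue
        if m.via == "synonym":
            via_synonym = True                  # rule 2
        if m.via == "subspecies":
            via_subspecies = True               # rule 3
        if m.taxon not in resolved:
            resolved.append(m.taxon)
    if dropped_nonregister:
        applied.append(1)
    if via_synonym:
        applied.append(2)
    if via_subspecies:
        applied.append(3)

    # rule 4: genus-level names give way to congeneric species-level names
    species_genera = {t.ancestor_at("genus") for t in resolved
                      if t.rank == "species"}
    pruned = [t for t in resolved
              if not (t.rank == "genus" and t.name in species_genera)]
    if len(pruned) != len(resolved):
        applied.append(4)
    resolved = pruned

    # rule 5: curated blocklist
    pruned = [t for t in resolved if t.name not in res.blocklist]
    if len(pruned) != len(resolved):
        applied.append(5)
    resolved = pruned

    # rule 6: one species matching consistently higher than the others
    if len(resolved) > 1 and not hits.empty:
        best = {}
        for t in resolved:
            mask = hits["lineage"].str.split("/").str[-1].isin(
                _name_variants(t, register))
            if mask.any():
                best[t.name] = float(hits.loc[mask, "pident"].max())
        if len(best) == len(resolved):
            ranked = sorted(best.items(), key=lambda kv: -kv[1])
            if ranked[0][1] - ranked[1][1] >= res.consistency_margin:
                resolved = [t for t in resolved if t.name == ranked[0][0]]
                applied.append(6)

    # rule 7: equal matches -> keep all (species complex)
    if len(resolved) > 1:
        applied.append(7)
    return resolved, applied


def _name_variants(taxon: TaxonRef, register: Register) -> set[str]:
    """All raw names that resolve to ``taxon`` (itself, synonyms, subspecies
    prefixes are matched by prefix below)."""
    variants = {taxon.name}
    for alt, canonical in getattr(register, "_synonyms", {}).items():
        if canonical == taxon.name:
            variants.add(alt)
    return variants


def lca_assign(hits: pd.DataFrame, cfg: AssignConfig, register: Register
               ) -> Optional[TaxonRef]:
    """Genus-capped LCA over top-percent candidate hits.

    Candidates: identity >= 80, coverage >= 80, bit-score > 170 and bit-score
    within 5% of the best candidate's (MEGAN-style top-percent filter, not
    the best five of the retrieved hits). Returns None when no candidate
    passes or the LCA is shallower than order.
    """
    if hits.empty:
        return None
    mask = ((hits["pident"] >= cfg.lca_min_identity)
            & (hits["qcovs"] >= cfg.lca_min_coverage)
            & (hits["bitscore"] > cfg.lca_min_bitscore))
    cand = hits.loc[mask]
    if cand.empty:
        return None
    cutoff = (1.0 - cfg.lca_top_fraction) * cand["bitscore"].max()
    cand = cand[cand["bitscore"] >= cutoff]
    taxa = [hit_taxon(l, register) for l in cand["lineage"]]
    lca = lowest_common_ancestor(taxa, max_rank=cfg.lca_rank_cap)
    if lca is None or lca.depth < RANK_DEPTH[cfg.min_accept_rank]:
        return None
    return lca


def screen_contaminants(wfd_hits: pd.DataFrame, genbank_hits: pd.DataFrame,
                        register: Register,
                        cfg: AssignConfig = AssignConfig()
                        ) -> tuple[bool, Optional[str]]:
    """Dual-database contaminant screen for one MOTU.

    Discards the MOTU when its best public-database hit outscores (bit-score)
    its best curated-database hit and that public hit's order is not among
    the register's orders (a non-macroinvertebrate such as *Homo sapiens* or
    *Wolbachia*). The target set is the register's order list, not a
    hard-coded taxon collection. Returns (keep, reason).
    """
    if genbank_hits.empty:
        return True, None
    best_gb = genbank_hits.loc[genbank_hits["bitscore"].idxmax()]
    best_wfd_score = wfd_hits["bitscore"].max() if not wfd_hits.empty else -np.inf
    if best_gb["bitscore"] <= best_wfd_score:
        return True, None
    order = str(best_gb["lineage"]).split("/")[0]
    if order in register.orders:
        return True, None
    return False, f"non-target: {str(best_gb['lineage']).split('/')[-1]}"


def assign_motu(motu: str, wfd_hits: pd.DataFrame, genbank_hits: pd.DataFrame,
                register: Register, cfg: AssignConfig = AssignConfig(),
                res: ResolutionConfig = ResolutionConfig(),
                reads: int = 0) -> AssignmentResult:
    """Run the full per-MOTU decision: screen, then direct path, else LCA."""
    keep, reason = screen_contaminants(wfd_hits, genbank_hits, register, cfg)
    if not keep:
        return AssignmentResult(motu, (), "discarded", reads=reads,
                                reason=reason)
    if wfd_hits.empty:
        return AssignmentResult(motu, (), "discarded", reads=reads,
                                reason="no hits")
    names = find_direct_hits(wfd_hits, cfg)
    if names:
        taxa, rules = resolve_direct(names, wfd_hits, register, res)
        if taxa:
            return AssignmentResult(motu, tuple(taxa), "direct",
                                    rules=tuple(rules), reads=reads)
    lca = lca_assign(wfd_hits, cfg, register)
    if lca is None:
        return AssignmentResult(motu, (), "discarded", reads=reads,
                                reason="above order")
    return AssignmentResult(motu, (lca,), "lca", reads=reads)


def assign_all(wfd_hits: pd.DataFrame, genbank_hits: pd.DataFrame,
               combined_counts: pd.DataFrame, replicates: pd.DataFrame,
               register: Register, cfg: AssignConfig = AssignConfig(),
               res: ResolutionConfig = ResolutionConfig()
               ) -> tuple[list[AssignmentResult], pd.DataFrame]:
    """Assign every MOTU in a combined (one column per sample) count table.

    Returns the per-MOTU results and a long-format aggregation with one row
    per (sample, taxon): MOTUs with the same final taxon are summed, so
    haplotype-split conspecific MOTUs collapse to one entry. Control samples
    are excluded from the aggregation.
    """
    wfd_by_motu = dict(tuple(wfd_hits.groupby("qseqid")))
    gb_by_motu = dict(tuple(genbank_hits.groupby("qseqid")))
    empty = wfd_hits.iloc[0:0]

    results: list[AssignmentResult] = []
    sample_cols = [c for c in combined_counts.columns
                   if not bool(replicates.loc[c, "is_control"])]
    for motu in combined_counts.index:
        w = wfd_by_motu.get(motu, empty)
        g = gb_by_motu.get(motu, genbank_hits.iloc[0:0])
        reads = int(combined_counts.loc[motu, sample_cols].sum())
        results.append(assign_motu(motu, w, g, register, cfg, res,
                                   reads=reads))
    return results, aggregate_assignments(results, combined_counts,
                                          replicates)


def aggregate_assignments(results: Sequence[AssignmentResult],
                          combined_counts: pd.DataFrame,
                          replicates: pd.DataFrame) -> pd.DataFrame:
    """Sum reads per (sample, final taxon) over assigned MOTUs; controls are
    excluded. Reusable on rarefied count tables without re-assigning."""
    sample_cols = [c for c in combined_counts.columns
                   if not bool(replicates.loc[c, "is_control"])]
    agg_rows = []
    for r in results:
        if r.taxon is None or r.motu not in combined_counts.index:
            continue
        row = combined_counts.loc[r.motu, sample_cols]
        for sample in row.index[row > 0]:
            agg_rows.append((sample,
                             replicates.loc[sample, "location"],
                             replicates.loc[sample, "group"],
                             r.taxon.name, r.taxon.rank,
                             int(row[sample])))
    agg = pd.DataFrame(agg_rows, columns=["sample", "location", "group",
                                          "taxon", "rank", "count"])
    if not agg.empty:
        agg = (agg.groupby(["sample", "location", "group", "taxon", "rank"],
                           as_index=False)["count"].sum())
    return agg


def results_frame(results: Sequence[AssignmentResult]) -> pd.DataFrame:
    """Tabular assignment report: motu, method, taxon, rank, rules, reads,
    reason. Unresolved complexes list all names slash-joined under their
    representative taxon's rank."""
    rows = []
    for r in results:
        taxon = r.taxon
        rows.append((r.motu, r.method,
                     " / ".join(t.name for t in r.taxa) if r.taxa else "",
                     taxon.rank if taxon is not None else "",
                     ",".join(map(str, r.rules)), r.reads, r.reason or ""))
    return pd.DataFrame(rows, columns=["motu", "method", "taxon", "rank",
                                       "rules", "reads", "reason"])


def aggregate_to_locations(agg: pd.DataFrame, origin: str,
                           pooled: bool = False) -> TaxonList:
    """Accumulate sample-level aggregated counts to location level.

    Sorted samples of one location are unioned (counts summed per taxon);
    pooled samples are kept as their own lists (``pooled=True`` selects the
    POOL group rows, False everything else).
    """
    sel = agg[agg["group"].eq("POOL") == pooled]
    if sel.empty:
        return TaxonList(pd.DataFrame(columns=list(TaxonList.COLUMNS)),
                         origin=origin)
    loc = (sel.groupby(["location", "group", "taxon", "rank"],
                       as_index=False)["count"].sum())
    return TaxonList(loc[["location", "group", "taxon", "rank", "count"]],
                     origin=origin)
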