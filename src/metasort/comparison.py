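"""Morphology-versus-DNA taxon-list concordance.

Every taxon occurring on the combined morphology and DNA lists of one
location is placed in exactly one of six categories:

1. ``found`` — exact match between the lists;
2. ``different_level`` — a match, but one list carries a higher-rank
   identification (genus on one side, a species of that genus on the other);
3. ``putative_misid`` — the lists carry different species of one genus;
4. ``missing_in_reference`` — a morphologically identified species with no
   coverage in the DNA reference database;
5. ``not_found`` — covered in the reference but seen only in morphology;
6. ``extra`` — seen only in the DNA list.

Categories 1–3 count as overlap; category 4 counts towards the
morphology-only fraction (such taxa can never be found by DNA), category 6
is the DNA-only fraction. Per-sample fractions are averaged unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .taxonomy import Register, TaxonList, TaxonRef

CATEGORIES = ("found", "different_level", "putative_misid",
              "missing_in_reference", "not_found", "extra")
OVERLAP_CATEGORIES = ("found", "different_level", "putative_misid")

ENTRY_COLUMNS = ("location", "group", "taxon_morph", "taxon_dna", "category")


class ComparisonError(ValueError):
    pass


def _refs(names: Iterable[str], register: Register) -> dict[str, TaxonRef]:
    out = {}
    unmatched = []
    for n in names:
        ref = register.get(n)
        if ref is None:
            unmatched.append(n)
        else:
            out[n] = ref
    if unmatched:
        raise ComparisonError(
            f"unmatched names present (canonicalise first): {sorted(unmatched)}")
    return out


def classify(morph: TaxonList, dna: TaxonList, refdb_species: frozenset[str],
             register: Register) -> pd.DataFrame:
    """Classify the combined lists of every location into the six categories.

    Both lists must already be register-matched and redundancy-removed.
    Matching is deterministic and proceeds in priority order per location:
    exact name matches first, then cross-rank lineage matches, then
    congeneric species pairs (alphabetical pairing on ties); leftovers fall
    into the single-list categories. Each occurrence lands in exactly one
    entry. Pair entries carry the morphology entry's group label.
    """
    all_names = set(morph.entries["taxon"]) | set(dna.entries["taxon"])
    refs = _refs(all_names, register)
    rows = []
    locations = sorted(set(morph.entries["location"])
                       | set(dna.entries["location"]))
    for loc in locations:
        m = morph.entries[morph.entries["location"] == loc]
        d = dna.entries[dna.entries["location"] == loc]
        m_open = {(r.taxon, r.group): r for r in
                  sorted(m.itertuples(index=False), key=lambda r: r.taxon)}
        d_open = {(r.taxon, r.group): r for r in
                  sorted(d.itertuples(index=False), key=lambda r: r.taxon)}

        # 1. exact taxon matches
        for mk in list(m_open):
            hits = [dk for dk in d_open if dk[0] == mk[0]]
            if hits:
                dk = hits[0]
                rows.append((loc, m_open[mk].group, mk[0], dk[0], "found"))
                del m_open[mk], d_open[dk]

        # 2. cross-rank lineage matches (one side identifies higher)
        for mk in list(m_open):
            a = refs[mk[0]]
            partner = None
            for dk in d_open:
                b = refs[dk[0]]
                if a.is_strict_ancestor_of(b) or b.is_strict_ancestor_of(a):
                    partner = dk
                    break
            if partner is not None:
                rows.append((loc, m_open[mk].group, mk[0], partner[0],
                             "different_level"))
                del m_open[mk], d_open[partner]

        # 3. congeneric species pairs (putative misidentifications)
        for mk in list(m_open):
            a = refs[mk[0]]
            if a.rank != "species":
                continue
            partner = None
            for dk in d_open:
                b = refs[dk[0]]
                if (b.rank == "species" and b.name != a.name
                        and b.ancestor_at("genus") == a.ancestor_at("genus")):
                    partner = dk
                    break
            if partner is not None:
                rows.append((loc, m_open[mk].group, mk[0], partner[0],
                             "putative_misid"))
                del m_open[mk], d_open[partner]

        # 4/5. morphology-only
        for mk, r in m_open.items():
            a = refs[mk[0]]
            if a.rank == "species" and a.name not in refdb_species:
                rows.append((loc, r.group, mk[0], "", "missing_in_reference"))
            else:
                rows.append((loc, r.group, mk[0], "", "not_found"))

        # 6. DNA-only
        for dk, r in d_open.items():
            rows.append((loc, r.group, "", dk[0], "extra"))

    return pd.DataFrame(rows, columns=list(ENTRY_COLUMNS))


def overlap_fractions(entries: pd.DataFrame) -> tuple[float, float, float]:
    """(overlap, morphology-only, DNA-only) fractions of one sample's entries.

    Overlap pools categories 1–3; ``missing_in_reference`` counts towards the
    morphology-only fraction. The three fractions sum to 1.
    """
    n = len(entries)
    if n == 0:
        raise ComparisonError("no entries: fractions undefined")
    c = entries["category"].value_counts()
    overlap = sum(int(c.get(k, 0)) for k in OVERLAP_CATEGORIES)
    morph_only = int(c.get("missing_in_reference", 0)) + int(c.get("not_found", 0))
    dna_only = int(c.get("extra", 0))
    return overlap / n, morph_only / n, dna_only / n


def category_shares(entries: pd.DataFrame,
                    categories: tuple[str, ...] = OVERLAP_CATEGORIES
                    ) -> dict[str, float]:
    """Share of each requested category within the requested categories
    (e.g. the direct-match share of the pooled overlap entries)."""
    sub = entries[entries["category"].isin(categories)]
    if sub.empty:
        raise ComparisonError("no entries in the requested categories")
    counts = sub["category"].value_counts()
    return {k: int(counts.get(k, 0)) / len(sub) for k in categories}


def exclude_failed(morph: TaxonList, failed: Iterable[tuple[str, str]]
                   ) -> tuple[TaxonList, pd.DataFrame]:
    """Remove morphology entries whose (location, group) sample failed to
    amplify — such taxa can only ever count as not found by DNA. Returns
    the pruned list and the removed rows (for per-group reporting)."""
    failed = set(failed)
    df = morph.entries
    mask = [(loc, grp) in failed
            for loc, grp in zip(df["location"], df["group"])]
    removed = df[mask].copy()
    kept = df[[not m for m in mask]].reset_index(drop=True)
    return TaxonList(kept, origin=morph.origin), removed


@dataclass
class ComparisonSummary:
    """Per-location fractions plus unweighted per-group and overall means."""

    per_location: pd.DataFrame   # location, n, overlap, morph_only, dna_only
    per_group: pd.DataFrame      # group, n_locations, mean/min/max fractions
    overall: dict[str, float]


def summarize(entries: pd.DataFrame) -> ComparisonSummary:
    """Unweighted mean and range of per-location fractions, overall and per
    group, plus counts of locations where one fraction dominates another."""
    per_loc_rows = []
    for loc, sub in entries.groupby("location"):
        ov, mo, do = overlap_fractions(sub)
        per_loc_rows.append((loc, len(sub), ov, mo, do))
    per_location = pd.DataFrame(
        per_loc_rows, columns=["location", "n", "overlap", "morph_only",
                               "dna_only"])

    group_rows = []
    for grp, sub in entries.groupby("group"):
        fracs = []
        for loc, s in sub.groupby("location"):
            fracs.append(overlap_fractions(s))
        arr = np.array(fracs)
        group_rows.append((grp, len(fracs), *arr.mean(axis=0),
                           arr[:, 0].min(), arr[:, 0].max()))
    per_group = pd.DataFrame(
        group_rows, columns=["group", "n_locations", "overlap", "morph_only",
                             "dna_only", "overlap_min", "overlap_max"])

    overall = {
        "n_locations": float(len(per_location)),
        "mean_entries": float(per_location["n"].mean()),
        "overlap": float(per_location["overlap"].mean()),
        "morph_only": float(per_location["morph_only"].mean()),
        "dna_only": float(per_location["dna_only"].mean()),
        "overlap_range": (float(per_location["overlap"].min()),
                          float(per_location["overlap"].max())),
        "n_morph_only_gt_overlap": int((per_location["morph_only"]
                                        > per_location["overlap"]).sum()),
        "n_dna_only_gt_morph_only": int((per_location["dna_only"]
                                         > per_location["morph_only"]).sum()),
    }
    return ComparisonSummary(per_location, per_group, overall)


def richness_stats(morph_richness: pd.Series, dna_richness: pd.Series
                   ) -> dict[str, float]:
    """Paired per-location richness comparison.

    Reports the Pearson correlation, the two means with ranges, the ratio of
    means and the mean of per-location ratios (both bases are reported since
    summary prose rarely states which one it used).
    """
    joined = pd.concat({"morph": morph_richness, "dna": dna_richness},
                       axis=1).dropna()
    if len(joined) < 3:
        raise ComparisonError("need at least 3 paired samples")
    out: dict[str, float] = {
        "n": float(len(joined)),
        "morph_mean": float(joined["morph"].mean()),
        "morph_min": float(joined["morph"].min()),
        "morph_max": float(joined["morph"].max()),
        "dna_mean": float(joined["dna"].mean()),
        "dna_min": float(joined["dna"].min()),
        "dna_max": float(joined["dna"].max()),
        "ratio_of_means": float(joined["dna"].mean() / joined["morph"].mean()),
        "mean_ratio": float((joined["dna"] / joined["morph"]).mean()),
    }
    if joined["morph"].nunique() == 1 or joined["dna"].nunique() == 1:
        out["pearson_r"] = float("nan")
    else:
        out["pearson_r"] = float(stats.pearsonr(joined["morph"],
                                                joined["dna"])[0])
    return out


def percent_gain(a: float, b: float) -> float:
    """Percent by which ``a`` exceeds ``b``: 100 * (a - b) / b."""
    if b == 0:
        raise ComparisonError("undefined percent gain with zero baseline")
    return 100.0 * (a - b) / b


def richness(taxa: TaxonList) -> pd.Series:
    """Distinct-taxon count per location."""
    return (taxa.entries.groupby("location")["taxon"].nunique()
            .rename("richness"))


def presence_absence(taxa: TaxonList) -> pd.DataFrame:
    """Location x taxon 0/1 matrix for export to external index calculators
    (scores there are computed on presence/absence, so all counts become 1)."""
    df = taxa.entries.assign(present=1)
    return (df.pivot_table(index="location", columns="taxon",
                           values="present", aggfunc="max", fill_value=0)
            .astype(int))
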