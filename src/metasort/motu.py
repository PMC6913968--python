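"""MOTU table processing and sequence QC stand-ins.

Covers the read-table half of an amplicon pipeline once reads have been
merged and primer-trimmed upstream: an amplicon length window, exact
dereplication with a minimum abundance, greedy centroid clustering into
Molecular Operational Taxonomic Units (MOTUs), a cross-contamination
threshold derived from an artificial internal control (AIC) spike-in,
per-replicate relative-abundance filtering, low-depth replicate discard,
additive replicate combination, and rarefaction.

The clustering here is a desk-scale greedy centroid algorithm with global
alignment identity — the same decision rule abundance-sorted centroid
clusterers apply, without their search heuristics; it is meant for simulated
or down-sampled inputs, not million-read libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
import pandas as pd


class MotuError(ValueError):
    """Raised for inconsistent tables or invalid filter configuration."""


@dataclass(frozen=True)
class QCConfig:
    """Sequence QC parameters.

    The defaults target a 316 bp COI fragment: reads three bases shorter or
    longer than the target pass (natural length variation plus primer
    slippage), singletons are removed before clustering, and clusters form at
    98% pairwise identity.
    """

    len_min: int = 313
    len_max: int = 319
    min_derep_abundance: int = 2
    cluster_identity: float = 0.98

    def __post_init__(self) -> None:
        if self.len_min > self.len_max:
            raise MotuError("len_min must be <= len_max")
        if not 0 < self.cluster_identity <= 1:
            raise MotuError("cluster_identity must be in (0, 1]")


@dataclass(frozen=True)
class FilterConfig:
    """MOTU-table filtering parameters.

    ``motu_rel_abundance_threshold`` is the per-replicate relative abundance
    at or below which a MOTU count is zeroed (strictly-above survives);
    0.00025 corresponds to the 0.025% contamination level observed with AIC
    spike-ins. Replicates with fewer than ``min_replicate_reads`` after
    filtering are discarded; surviving replicates are combined additively.
    """

    motu_rel_abundance_threshold: float = 0.00025
    min_replicate_reads: int = 4000
    replicate_combination: str = "additive"

    def __post_init__(self) -> None:
        if not 0 <= self.motu_rel_abundance_threshold < 1:
            raise MotuError("threshold must be in [0, 1)")
        if self.replicate_combination != "additive":
            raise MotuError("only the additive combination strategy is supported")


@dataclass
class MotuTable:
    """Per-replicate MOTU read counts plus replicate and MOTU metadata.

    ``counts``: DataFrame, index = MOTU ids, columns = replicate ids.
    ``replicates``: DataFrame indexed by replicate id with columns
    sample, location, group, replicate, is_control.
    ``motus``: DataFrame indexed by MOTU id with at least is_control_sequence
    (True for the AIC construct) and optionally a sequence id.
    """

    counts: pd.DataFrame
    replicates: pd.DataFrame
    motus: pd.DataFrame

    def __post_init__(self) -> None:
        if set(self.counts.columns) != set(self.replicates.index):
            raise MotuError("counts columns and replicate metadata disagree")
        if set(self.counts.index) != set(self.motus.index):
            raise MotuError("counts index and MOTU metadata disagree")
        if (self.counts.to_numpy() < 0).any():
            raise MotuError("negative read counts")
        self.counts = self.counts.astype(np.int64)

    @property
    def aic_motus(self) -> pd.Index:
        return self.motus.index[self.motus["is_control_sequence"].astype(bool)]

    @property
    def control_replicates(self) -> pd.Index:
        return self.replicates.index[self.replicates["is_control"].astype(bool)]

    def replicate_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def copy(self) -> "MotuTable":
        return MotuTable(self.counts.copy(), self.replicates.copy(),
                         self.motus.copy())

    def drop_empty_motus(self) -> "MotuTable":
        keep = self.counts.sum(axis=1) > 0
        return MotuTable(self.counts.loc[keep], self.replicates.copy(),
                         self.motus.loc[keep].copy())


# ---------------------------------------------------------------------------
# sequence-level QC


def filter_by_length(sequences: Iterable[str], cfg: QCConfig = QCConfig()
                     ) -> list[str]:
    """Keep sequences inside the inclusive window [len_min, len_max]."""
    return [s for s in sequences if cfg.len_min <= len(s) <= cfg.len_max]


def dereplicate(sequences: Iterable[str], cfg: QCConfig = QCConfig()
                ) -> list[tuple[str, int]]:
    """Exact-identity dereplication with a minimum abundance.

    Returns (sequence, abundance) pairs sorted by abundance descending, ties
    broken by first occurrence; groups below ``min_derep_abundance`` are
    dropped (singleton removal at the default of 2).
    """
    counts: dict[str, int] = {}
    order: dict[str, int] = {}
    for i, s in enumerate(sequences):
        if s not in counts:
            counts[s] = 0
            order[s] = i
        counts[s] += 1
    items = [(s, n) for s, n in counts.items() if n >= cfg.min_derep_abundance]
    items.sort(key=lambda sn: (-sn[1], order[sn[0]]))
    return items


def pairwise_identity(a: str, b: str) -> float:
    """Global pairwise identity: 1 - (edit distance / longer length).

    Unit-cost global alignment via edlib. Dividing by the longer sequence
    length (the minimum possible alignment span) keeps the value independent
    of which co-optimal traceback the aligner happens to return: for
    substitution-only differences this is exactly matching columns over
    alignment columns (e.g. 10 mismatches over 316 bp -> 306/316).
    """
    if a == b:
        return 1.0
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


@dataclass
class Cluster:
    centroid: str
    abundance: int
    members: list[str] = field(default_factory=list)


def greedy_cluster(dereplicated: Sequence[tuple[str, int]],
                   cfg: QCConfig = QCConfig()) -> list[Cluster]:
    """Abundance-ordered greedy centroid clustering.

    Each sequence (visited in abundance-descending order) joins the first
    existing centroid whose global-alignment identity is at least
    ``cluster_identity``; otherwise it founds a new centroid.
    """
    clusters: list[Cluster] = []
    for seq, abundance in dereplicated:
        for cl in clusters:
            if pairwise_identity(seq, cl.centroid) >= cfg.cluster_identity:
                cl.members.append(seq)
                cl.abundance += abundance
                break
        else:
            clusters.append(Cluster(centroid=seq, abundance=abundance,
                                    members=[seq]))
    return clusters


# ---------------------------------------------------------------------------
# table-level filtering


def determine_contamination_threshold(table: MotuTable) -> float:
    """Smallest relative-abundance cutoff that removes all cross-contamination.

    Offending cells are AIC reads in regular replicates and non-AIC reads in
    control replicates. Zeroing every MOTU with relative abundance <= t (per
    replicate, against the raw replicate total) eliminates all offenders
    exactly when t is the maximum offending relative abundance; that maximum
    is returned (0.0 with no cross-contamination).
    """
    controls = table.control_replicates
    if len(controls) == 0:
        raise MotuError("no control replicates: cannot derive a threshold")
    aic = table.aic_motus
    totals = table.replicate_totals()
    worst = 0.0
    for rep in table.counts.columns:
        total = totals[rep]
        if total == 0:
            continue
        col = table.counts[rep]
        if rep in set(controls):
            offending = col.drop(index=aic)
        else:
            offending = col.loc[aic]
        if len(offending):
            worst = max(worst, offending.max() / total)
    return float(worst)


def filter_low_abundance(table: MotuTable,
                         cfg: FilterConfig = FilterConfig()) -> MotuTable:
    """Zero MOTU counts at or below the relative-abundance threshold.

    The denominator is the replicate total before any MOTU filtering; a MOTU
    survives only if its share is strictly above the threshold.
    """
    out = table.copy()
    totals = table.replicate_totals()
    t = cfg.motu_rel_abundance_threshold
    for rep in out.counts.columns:
        total = totals[rep]
        if total == 0:
            continue
        col = out.counts[rep]
        out.counts[rep] = col.where(col / total > t, 0)
    return out


def discard_and_combine(table: MotuTable,
                        cfg: FilterConfig = FilterConfig()
                        ) -> tuple[MotuTable, pd.DataFrame]:
    """Drop low-depth replicates and combine the rest additively per sample.

    Replicates whose post-filter total is strictly below
    ``min_replicate_reads`` are discarded. Surviving replicates of one sample
    are summed (the additive strategy: a MOTU counts no matter how many
    replicates it occurred in). Samples with no surviving replicate are
    excluded and returned in the failed-sample registry.
    """
    totals = table.replicate_totals()
    keep = totals[totals >= cfg.min_replicate_reads].index
    samples = table.replicates.loc[list(table.counts.columns), "sample"]

    merged: dict[str, pd.Series] = {}
    meta_rows = []
    failed_rows = []
    for sample, reps in samples.groupby(samples):
        rep_ids = [r for r in reps.index if r in set(keep)]
        info = table.replicates.loc[reps.index[0]]
        if not rep_ids:
            failed_rows.append((sample, info["location"], info["group"],
                                bool(info["is_control"]), len(reps)))
            continue
        merged[sample] = table.counts[rep_ids].sum(axis=1)
        meta_rows.append((sample, sample, info["location"], info["group"],
                          0, bool(info["is_control"]), len(rep_ids)))

    counts = pd.DataFrame(merged, index=table.counts.index)
    replicates = pd.DataFrame(
        meta_rows, columns=["id", "sample", "location", "group", "replicate",
                            "is_control", "n_replicates"]).set_index("id")
    failed = pd.DataFrame(
        failed_rows, columns=["sample", "location", "group", "is_control",
                              "n_replicates"])
    combined = MotuTable(counts, replicates, table.motus.copy())
    return combined, failed


def rarefy(counts: pd.Series, depth: int,
           rng: np.random.Generator | int) -> pd.Series:
    """Subsample reads without replacement to exactly ``depth``.

    Multivariate hypergeometric draw; deterministic under a fixed generator
    state. Raises when the total is below the requested depth so the caller
    can decide to skip (and report) the sample.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    total = int(counts.sum())
    if total < depth:
        raise MotuError(f"total {total} below rarefaction depth {depth}")
    if total == depth:
        return counts.copy()
    drawn = rng.multivariate_hypergeometric(counts.to_numpy(dtype=np.int64),
                                            depth)
    return pd.Series(drawn, index=counts.index)


def rarefy_table(table: MotuTable, depths: dict[str, int] | int,
                 seed: int) -> tuple[MotuTable, list[str]]:
    """Rarefy each sample column to its target depth.

    ``depths`` maps sample id -> depth (or one depth for all). Samples whose
    total falls short are kept unrarefied and listed in the second return
    value. One child generator per sample keeps the draw independent of
    column order.
    """
    out = table.copy()
    skipped: list[str] = []
    root = np.random.default_rng(seed)
    streams = root.spawn(len(out.counts.columns))
    for rep, rng in zip(out.counts.columns, streams):
        depth = depths if isinstance(depths, int) else depths.get(rep)
        if depth is None:
            continue
        try:
            out.counts[rep] = rarefy(out.counts[rep], depth, rng)
        except MotuError:
            skipped.append(rep)
    return out, skipped


def run_filtering(table: MotuTable, cfg: FilterConfig = FilterConfig(),
                  threshold: Optional[float] = None
                  ) -> tuple[MotuTable, pd.DataFrame, float]:
    """Fixed-order pipeline: threshold filter -> replicate discard -> merge.

    When ``threshold`` is None it is derived from the internal control via
    :func:`determine_contamination_threshold`. Returns the combined table,
    the failed-sample registry and the threshold actually applied.
    """
    if threshold is None:
        threshold = determine_contamination_threshold(table)
    eff = replace(cfg, motu_rel_abundance_threshold=threshold)
    filtered = filter_low_abundance(table, eff)
    combined, failed = discard_and_combine(filtered, eff)
    return combined, failed, threshold
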