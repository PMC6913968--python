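"""Synthetic metabarcoding study generator with full ground truth.

Emulates the statistical structure of a taxonomically sorted freshwater
macroinvertebrate monitoring survey: per-location communities sorted into six
groups (ANNE, CRUS, HECO, MOLL, TOE, REST), each sequenced separately in two
PCR replicates and together as an equal-volume pool, plus artificial
internal control (AIC) replicates. The generator injects the failure modes
the pipeline must withstand:

* lognormal biomass and per-species amplification jitter;
* group-level preferential amplification in pools (a heavy-tailed per-group
  factor producing single-group and single-taxon read dominance — the
  mechanism by which pooling loses taxa);
* haplotype splitting of species into several MOTUs and low-abundance
  pseudogene MOTUs that only resolve to genus level;
* reference-database coverage gaps (per-group coverage fractions);
* AIC cross-contamination into regular replicates and foreign reads in
  control replicates;
* whole-sample amplification failures (elevated for molluscs);
* off-target contaminant MOTUs (human, *Wolbachia*) visible only to the
  public reference database;
* morphological noise: congeneric misidentification swaps and genus-level
  resolution limits.

Hit-table identities are drawn from fixed bands per situation rather than
from simulated sequences; sequence-level simulation (`simulate_reads`) is
provided separately to exercise the clustering kernel.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .taxonomy import GROUPS, Register, TaxonList
from .motu import MotuTable

_EPITHETS = "aquaticus|palustris|lacustris|fluviatilis|riparius|stagnalis"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation parameters.

    Defaults reflect a 25-location survey with two PCR replicates per sample,
    mean replicate depths around 28,000 reads, reference coverage of 63.5%
    for annelids and 96.5% for the TOE group (86% elsewhere), and elevated
    amplification failure for molluscs.
    """

    seed: int = 0
    n_locations: int = 25

    # community structure
    group_pool_sizes: tuple[int, ...] = (60, 40, 60, 45, 70, 90)  # per GROUPS
    mean_richness: tuple[float, ...] = (6.0, 6.0, 8.0, 7.0, 8.0, 12.0)
    species_per_genus_p: float = 0.45      # geometric; mean ~2.2 congeners
    genera_per_family: int = 3
    families_per_order: int = 3
    synonym_rate: float = 0.08
    foreign_congener_rate: float = 0.15    # non-register species in the refdb

    # reference database coverage (ANNE, CRUS, HECO, MOLL, TOE, REST)
    ref_coverage: tuple[float, ...] = (0.635, 0.86, 0.86, 0.86, 0.965, 0.86)

    # read generation
    biomass_sigma: float = 1.5
    species_amp_sigma: float = 1.5
    group_amp_sigma: float = 2.5           # pooled dominance parameter
    amplification_dropout: float = 0.12    # species the primers barely amplify
    dropout_factor: float = 1e-3
    haplotype_p: float = 0.65              # geometric; mean ~1.5 MOTUs/species
    max_haplotypes: int = 3
    pseudogene_rate: float = 0.15
    pseudogene_fraction: float = 0.03      # of the parent species' reads
    sorted_depth_mean: float = 28345.0
    sorted_depth_sigma: float = 0.35
    pooled_depth_mean: float = 28641.0
    pooled_depth_sigma: float = 0.45
    failed_depth_range: tuple[int, int] = (300, 3500)

    # failure probabilities per GROUPS order, then the pool
    failure_probs: tuple[float, ...] = (0.16, 0.04, 0.12, 0.54, 0.04, 0.0)
    pool_failure_prob: float = 0.04

    # contamination
    n_control_samples: int = 2
    aic_contamination_rate: float = 0.15   # per regular replicate
    aic_contamination_max_frac: float = 2.5e-4
    control_foreign_rate: float = 0.5      # per control replicate
    control_foreign_max_frac: float = 2.0e-4
    contaminant_rate: float = 0.3          # off-target MOTU per location

    # hit-table identity bands (percent)
    direct_identity_band: tuple[float, float] = (98.6, 100.0)
    congener_identity_band: tuple[float, float] = (85.0, 93.0)
    pseudogene_identity_band: tuple[float, float] = (88.0, 95.0)
    cross_genus_rate: float = 0.05         # LCA ambiguity up to family
    competing_direct_rate: float = 0.05    # second register congener >98%
    foreign_direct_rate: float = 0.10      # rule-1 fodder
    synonym_hit_rate: float = 0.5          # hits reported under the synonym

    # morphology noise
    misid_rate: float = 0.06
    genus_only_rate: float = 0.08
    morph_miss_rate: float = 0.10          # taxa overlooked by the assessor

    def __post_init__(self) -> None:
        for p in (self.haplotype_p, self.misid_rate, self.genus_only_rate,
                  self.pool_failure_prob, *self.failure_probs,
                  *self.ref_coverage):
            if not 0 <= p <= 1:
                raise SimulationError("probabilities must lie in [0, 1]")
        if len(self.group_pool_sizes) != len(GROUPS):
            raise SimulationError("one pool size per group required")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    communities: dict[str, list[str]]          # "loc|group" -> species
    motu_species: dict[str, str]               # motu -> species name
    motu_kind: dict[str, str]                  # haplotype|pseudogene|contaminant|aic
    uncovered_species: list[str]
    dropout_species: list[str]
    swaps: list[dict]                          # location, group, true, recorded
    genus_only: list[dict]                     # location, group, species, genus
    morph_misses: list[dict]                   # taxa the assessor overlooked
    forced_failures: list[str]                 # sample ids
    aic_injections: list[dict]                 # replicate, count
    foreign_in_controls: list[dict]
    contaminant_cells: list[dict]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))

    def community(self, location: str, group: str) -> list[str]:
        return self.communities.get(f"{location}|{group}", [])


@dataclass
class SimulatedStudy:
    """Bundle of generated inputs plus ground truth."""

    config: SimConfig
    register: Register
    refdb_species: frozenset[str]
    table: MotuTable
    wfd_hits: pd.DataFrame
    genbank_hits: pd.DataFrame
    morphology: TaxonList
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.register.to_csv(outdir / "register.csv")
        pd.Series(sorted(self.refdb_species), name="species").to_csv(
            outdir / "refdb_species.csv", index=False)
        self.table.counts.rename_axis("motu").to_csv(
            outdir / "motu_counts.tsv", sep="\t")
        self.table.replicates.rename_axis("replicate").to_csv(
            outdir / "replicates.csv")
        self.table.motus.rename_axis("motu").to_csv(outdir / "motus.csv")
        self.wfd_hits.to_csv(outdir / "hits_wfd.tsv", sep="\t", index=False)
        self.genbank_hits.to_csv(outdir / "hits_genbank.tsv", sep="\t",
                                 index=False)
        self.morphology.to_csv(outdir / "morphology.csv")
        self.truth.to_json(outdir / "truth.json")


# ---------------------------------------------------------------------------
# taxonomy construction


def _build_taxonomy(cfg: SimConfig, rng: np.random.Generator
                    ) -> tuple[Register, dict[str, list[str]],
                               dict[str, str], dict[str, str]]:
    """Create the ranked register: per-group pools of binomial species nested
    in genera/families/orders, plus synonyms and non-register (foreign)
    congeners that exist only in the reference database.

    Returns (register, group -> species pool, species -> synonym used in hit
    tables, species -> group).
    """
    reg = Register()
    pools: dict[str, list[str]] = {}
    synonyms: dict[str, str] = {}
    species_group: dict[str, str] = {}
    epithets = _EPITHETS.split("|")
    for gi, group in enumerate(GROUPS):
        n_species = cfg.group_pool_sizes[gi]
        made = 0
        order_i = family_i = genus_i = 0
        while made < n_species:
            order_i += 1
            order = f"{group.capitalize()}iformes{order_i}"
            reg.add(order, "order")
            for _ in range(cfg.families_per_order):
                if made >= n_species:
                    break
                family_i += 1
                family = f"{group.capitalize()}idae{family_i}"
                reg.add(family, "family", parent=order)
                for _ in range(cfg.genera_per_family):
                    if made >= n_species:
                        break
                    genus_i += 1
                    genus = f"{group.capitalize()}us{genus_i}"
                    reg.add(genus, "genus", parent=family)
                    k = min(int(rng.geometric(cfg.species_per_genus_p)),
                            n_species - made, 4)
                    for si in range(k):
                        epi = f"{epithets[si % len(epithets)]}{made + 1}"
                        name = f"{genus} {epi}"
                        reg.add(name, "species", parent=genus)
                        pools.setdefault(group, []).append(name)
                        species_group[name] = group
                        made += 1
                        if rng.random() < cfg.synonym_rate:
                            alt = f"{genus}ella {epi}"
                            reg.add_synonym(alt, name)
                            synonyms[name] = alt
                    if rng.random() < cfg.foreign_congener_rate:
                        foreign = f"{genus} peregrinus{genus_i}"
                        reg.add(foreign, "species", parent=genus,
                                in_register=False)
    # off-target lineages seen only through the public database
    reg.add("Primates", "order", in_register=False)
    reg.add("Hominidae", "family", parent="Primates", in_register=False)
    reg.add("Homo", "genus", parent="Hominidae", in_register=False)
    reg.add("Homo sapiens", "species", parent="Homo", in_register=False)
    reg.add("Rickettsiales", "order", in_register=False)
    reg.add("Anaplasmataceae", "family", parent="Rickettsiales",
            in_register=False)
    reg.add("Wolbachia", "genus", parent="Anaplasmataceae", in_register=False)
    reg.add("Wolbachia pipientis", "species", parent="Wolbachia",
            in_register=False)
    reg.add("Artiodactyla", "order", in_register=False)
    reg.add("Cervidae", "family", parent="Artiodactyla", in_register=False)
    reg.add("Muntiacus", "genus", parent="Cervidae", in_register=False)
    reg.add("Muntiacus reevesi", "species", parent="Muntiacus",
            in_register=False)
    return reg, pools, synonyms, species_group


def _lognormal_mean(rng: np.random.Generator, mean: float, sigma: float,
                    size: Optional[int] = None):
    """Lognormal draw parameterised by its arithmetic mean."""
    mu = np.log(mean) - sigma ** 2 / 2.0
    return rng.lognormal(mu, sigma, size)


# ---------------------------------------------------------------------------
# main generator


def simulate_study(cfg: SimConfig = SimConfig()) -> SimulatedStudy:
    """Generate one full synthetic study; bit-reproducible under cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    register, pools, synonyms, species_group = _build_taxonomy(cfg, rng)

    # reference coverage per group
    refdb: set[str] = set()
    uncovered: list[str] = []
    for gi, group in enumerate(GROUPS):
        for sp in pools[group]:
            if rng.random() < cfg.ref_coverage[gi]:
                refdb.add(sp)
            else:
                uncovered.append(sp)
    for t in register:
        if t.rank == "species" and not t.in_register:
            refdb.add(t.name)          # foreign species exist in the refdb

    locations = [f"L{i + 1:02d}" for i in range(cfg.n_locations)]

    # communities
    communities: dict[str, list[str]] = {}
    for loc in locations:
        for gi, group in enumerate(GROUPS):
            pool = pools[group]
            size = int(min(max(1, rng.poisson(cfg.mean_richness[gi])),
                           len(pool)))
            picks = sorted(rng.choice(len(pool), size=size, replace=False))
            communities[f"{loc}|{group}"] = [pool[i] for i in picks]

    # MOTU registry over the union of observed species
    observed = sorted({sp for com in communities.values() for sp in com})
    motu_species: dict[str, str] = {}
    motu_kind: dict[str, str] = {}
    species_motus: dict[str, list[tuple[str, float]]] = {}
    midx = 0
    for sp in observed:
        k = int(min(rng.geometric(cfg.haplotype_p), cfg.max_haplotypes))
        weights = rng.dirichlet(np.ones(k) * 2.0)
        parts: list[tuple[str, float]] = []
        for w in weights:
            midx += 1
            mid = f"motu_{midx:05d}"
            motu_species[mid] = sp
            motu_kind[mid] = "haplotype"
            parts.append((mid, float(w)))
        if rng.random() < cfg.pseudogene_rate:
            midx += 1
            mid = f"motu_{midx:05d}"
            motu_species[mid] = sp
            motu_kind[mid] = "pseudogene"
            parts = [(m, w * (1 - cfg.pseudogene_fraction)) for m, w in parts]
            parts.append((mid, cfg.pseudogene_fraction))
        species_motus[sp] = parts
    contaminant_motus = {}
    for name in ("Homo sapiens", "Wolbachia pipientis"):
        midx += 1
        mid = f"motu_{midx:05d}"
        motu_species[mid] = name
        motu_kind[mid] = "contaminant"
        contaminant_motus[name] = mid
    aic_motu = "motu_AIC"
    motu_species[aic_motu] = "Muntiacus reevesi"
    motu_kind[aic_motu] = "aic"
    motu_ids = list(motu_species)
    motu_pos = {m: i for i, m in enumerate(motu_ids)}

    # species the primer set essentially fails on (sequence-intrinsic, so
    # global across locations and shared by sorted and pooled routes)
    dropout = sorted(sp for sp in observed
                     if rng.random() < cfg.amplification_dropout)

    # per-(species, location) biomass and amplification jitter
    biomass: dict[tuple[str, str], float] = {}
    for loc in locations:
        for group in GROUPS:
            for sp in communities[f"{loc}|{group}"]:
                b = float(_lognormal_mean(rng, 1.0, cfg.biomass_sigma))
                j = float(np.exp(rng.normal(0.0, cfg.species_amp_sigma)))
                if sp in dropout:
                    j *= cfg.dropout_factor
                biomass[(sp, loc)] = b * j

    # replicate metadata + depths
    rep_rows = []
    depths: dict[str, int] = {}
    forced_failures: list[str] = []

    def _depth(mean: float, sigma: float) -> int:
        return int(max(4000, round(float(_lognormal_mean(rng, mean, sigma)))))

    for loc in locations:
        for gi, group in enumerate(GROUPS):
            sample = f"{loc}_{group}"
            fail = rng.random() < cfg.failure_probs[gi]
            if fail:
                forced_failures.append(sample)
            for r in (1, 2):
                rep = f"{sample}_r{r}"
                rep_rows.append((rep, sample, loc, group, r, False))
                depths[rep] = (int(rng.integers(*cfg.failed_depth_range))
                               if fail else
                               _depth(cfg.sorted_depth_mean,
                                      cfg.sorted_depth_sigma))
        sample = f"{loc}_POOL"
        fail = rng.random() < cfg.pool_failure_prob
        if fail:
            forced_failures.append(sample)
        for r in (1, 2):
            rep = f"{sample}_r{r}"
            rep_rows.append((rep, sample, loc, "POOL", r, False))
            depths[rep] = (int(rng.integers(*cfg.failed_depth_range))
                           if fail else
                           _depth(cfg.pooled_depth_mean,
                                  cfg.pooled_depth_sigma))
    for c in range(cfg.n_control_samples):
        sample = f"AIC_{c + 1}"
        for r in (1, 2):
            rep = f"{sample}_r{r}"
            rep_rows.append((rep, sample, "CTRL", "CTRL", r, True))
            depths[rep] = _depth(cfg.sorted_depth_mean, cfg.sorted_depth_sigma)
    replicates = pd.DataFrame(
        rep_rows, columns=["id", "sample", "location", "group", "replicate",
                           "is_control"]).set_index("id")

    # read counts
    counts = np.zeros((len(motu_ids), len(replicates)), dtype=np.int64)
    rep_pos = {r: j for j, r in enumerate(replicates.index)}

    def _motu_weights(sp_weights: dict[str, float]) -> np.ndarray:
        w = np.zeros(len(motu_ids))
        for sp, share in sp_weights.items():
            for mid, frac in species_motus[sp]:
                w[motu_pos[mid]] = share * frac
        return w / w.sum()

    group_amp: dict[tuple[str, str], float] = {}
    for loc in locations:
        for group in GROUPS:
            group_amp[(loc, group)] = float(
                np.exp(rng.normal(0.0, cfg.group_amp_sigma)))

        # sorted samples: within-group biomass structure only
        for group in GROUPS:
            com = communities[f"{loc}|{group}"]
            shares = {sp: biomass[(sp, loc)] for sp in com}
            w = _motu_weights(shares)
            for r in (1, 2):
                rep = f"{loc}_{group}_r{r}"
                counts[:, rep_pos[rep]] += rng.multinomial(depths[rep], w)

        # pooled sample: the same communities compounded by group factors
        shares = {}
        for group in GROUPS:
            com = communities[f"{loc}|{group}"]
            total = sum(biomass[(sp, loc)] for sp in com)
            for sp in com:
                shares[sp] = (biomass[(sp, loc)] / total
                              * group_amp[(loc, group)])
        w = _motu_weights(shares)
        for r in (1, 2):
            rep = f"{loc}_POOL_r{r}"
            counts[:, rep_pos[rep]] += rng.multinomial(depths[rep], w)

    # control replicates: all AIC reads
    for c in range(cfg.n_control_samples):
        for r in (1, 2):
            rep = f"AIC_{c + 1}_r{r}"
            counts[motu_pos[aic_motu], rep_pos[rep]] = depths[rep]

    # cross-contamination injections
    aic_injections: list[dict] = []
    foreign_in_controls: list[dict] = []
    contaminant_cells: list[dict] = []
    regular_reps = [r for r in replicates.index
                    if not replicates.loc[r, "is_control"]]
    real_motus = [m for m, k in motu_kind.items() if k == "haplotype"]
    failed_reps = {f"{s}_r{r}" for s in forced_failures for r in (1, 2)}
    for rep in regular_reps:
        # failed PCRs amplify no template, the spike-in included
        if rep in failed_reps:
            continue
        if rng.random() < cfg.aic_contamination_rate:
            frac = rng.uniform(1e-5, cfg.aic_contamination_max_frac)
            n = max(1, int(round(frac * depths[rep])))
            counts[motu_pos[aic_motu], rep_pos[rep]] += n
            aic_injections.append({"replicate": rep, "count": int(n)})
    for rep in replicates.index[replicates["is_control"]]:
        if rng.random() < cfg.control_foreign_rate:
            frac = rng.uniform(1e-5, cfg.control_foreign_max_frac)
            n = max(1, int(round(frac * depths[rep])))
            src = real_motus[int(rng.integers(len(real_motus)))]
            counts[motu_pos[src], rep_pos[rep]] += n
            foreign_in_controls.append({"replicate": rep, "motu": src,
                                        "count": int(n)})
    for loc in locations:
        if rng.random() < cfg.contaminant_rate:
            name = ("Homo sapiens" if rng.random() < 0.5
                    else "Wolbachia pipientis")
            mid = contaminant_motus[name]
            rep = f"{loc}_POOL_r{int(rng.integers(1, 3))}"
            frac = rng.uniform(0.002, 0.01)
            n = max(1, int(round(frac * depths[rep])))
            counts[motu_pos[mid], rep_pos[rep]] += n
            contaminant_cells.append({"replicate": rep, "motu": mid,
                                      "count": int(n)})

    count_df = pd.DataFrame(counts, index=motu_ids,
                            columns=list(replicates.index))
    motu_meta = pd.DataFrame({
        "is_control_sequence": [motu_kind[m] == "aic" for m in motu_ids],
        "sequence_id": [f"seq_{m}" for m in motu_ids],
    }, index=motu_ids)
    table = MotuTable(count_df, replicates, motu_meta)

    wfd_hits, genbank_hits = _build_hit_tables(
        cfg, rng, register, refdb, synonyms, motu_species, motu_kind)

    morphology, swaps, genus_only, misses = _build_morphology(
        cfg, rng, register, communities, locations)

    truth = GroundTruth(
        communities=communities,
        motu_species=motu_species,
        motu_kind=motu_kind,
        uncovered_species=uncovered,
        dropout_species=dropout,
        swaps=swaps,
        genus_only=genus_only,
        morph_misses=misses,
        forced_failures=forced_failures,
        aic_injections=aic_injections,
        foreign_in_controls=foreign_in_controls,
        contaminant_cells=contaminant_cells,
    )
    return SimulatedStudy(cfg, register, frozenset(refdb), table,
                          wfd_hits, genbank_hits, morphology, truth)


# ---------------------------------------------------------------------------
# hit tables


def _bitscore(pident: float) -> float:
    """Monotone identity -> bit-score map for a ~316 bp amplicon: roughly 580
    at a perfect match, ~490 at 85%, dropping below the 170 floor near 50%."""
    return round(6.3 * pident - 50.0, 1)


def _lineage(register: Register, name: str, synonym_of: Optional[str] = None
             ) -> str:
    ref = register.resolve(synonym_of or name)
    parts = list(ref.lineage)
    if synonym_of is not None:
        parts[-1] = name
    return "/".join(parts)


def _build_hit_tables(cfg, rng, register: Register, refdb: set[str],
                      synonyms: dict[str, str], motu_species: dict[str, str],
                      motu_kind: dict[str, str]
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    wfd_rows: list[tuple] = []
    gb_rows: list[tuple] = []

    def wfd(motu, name, pident, bitscore=None, qcovs=100.0, synonym_of=None):
        wfd_rows.append((motu, f"ref_{len(wfd_rows):06d}", round(pident, 2),
                         qcovs, bitscore if bitscore is not None
                         else _bitscore(pident),
                         _lineage(register, name, synonym_of)))

    def gb(motu, name, pident, bitscore, qcovs=100.0):
        gb_rows.append((motu, f"gb_{len(gb_rows):06d}", round(pident, 2),
                        qcovs, bitscore, _lineage(register, name)))

    species_by_genus: dict[str, list[str]] = {}
    for t in register:
        if t.rank == "species":
            species_by_genus.setdefault(t.ancestor_at("genus"), []).append(t.name)
    genera_by_family: dict[str, list[str]] = {}
    for t in register:
        if t.rank == "genus":
            genera_by_family.setdefault(t.ancestor_at("family"), []).append(t.name)

    for motu, sp in motu_species.items():
        kind = motu_kind[motu]
        ref = register.resolve(sp)
        genus = ref.ancestor_at("genus")
        congeners = [s for s in species_by_genus.get(genus, [])
                     if s != sp and s in refdb]

        if kind == "aic":
            gb(motu, "Muntiacus reevesi", 99.8, 620.0)
            continue
        if kind == "contaminant":
            gb(motu, sp, rng.uniform(99.0, 100.0), 600.0)
            # a spurious weak curated-database hit, below every threshold
            weak = sorted(s for s in refdb if register.resolve(s).in_register)
            name = weak[int(rng.integers(len(weak)))]
            wfd(motu, name, rng.uniform(75.0, 82.0),
                bitscore=rng.uniform(140.0, 168.0),
                qcovs=rng.uniform(60.0, 79.0))
            continue

        covered = sp in refdb
        if kind == "haplotype" and covered:
            p = rng.uniform(*cfg.direct_identity_band)
            syn = synonyms.get(sp)
            if syn is not None and rng.random() < cfg.synonym_hit_rate:
                wfd(motu, syn, p, synonym_of=sp)
            else:
                wfd(motu, sp, p)
            if congeners and rng.random() < cfg.competing_direct_rate:
                q = max(98.05, p - rng.uniform(0.6, 1.5))
                wfd(motu, congeners[0], q)
            foreign = [s for s in species_by_genus.get(genus, [])
                       if not register.resolve(s).in_register]
            if foreign and rng.random() < cfg.foreign_direct_rate:
                wfd(motu, foreign[0], max(98.05, p - rng.uniform(0.0, 0.5)))
            for c in congeners[:2]:
                wfd(motu, c, rng.uniform(*cfg.congener_identity_band))
            best = max(r[4] for r in wfd_rows if r[0] == motu)
            gb(motu, sp, p - 0.1, best - 5.0)
            continue

        # pseudogene, or haplotype of an uncovered species: sub-direct hits
        band = (cfg.pseudogene_identity_band if kind == "pseudogene"
                else cfg.congener_identity_band)
        targets = congeners if not covered else [sp] + congeners
        if not targets:
            # genus entirely absent: hits land on other genera of the family
            family = ref.ancestor_at("family")
            other = [g for g in genera_by_family.get(family, []) if g != genus
                     and species_by_genus.get(g)]
            targets = ([species_by_genus[g][0] for g in other[:2]]
                       or [sp])  # last resort: itself at low identity
        best_p = rng.uniform(*band)
        wfd(motu, targets[0], best_p)
        for t in targets[1:3]:
            wfd(motu, t, max(band[0], best_p - rng.uniform(0.5, 3.0)))
        if rng.random() < cfg.cross_genus_rate:
            family = ref.ancestor_at("family")
            other = [g for g in genera_by_family.get(family, []) if g != genus
                     and species_by_genus.get(g)]
            if other:
                wfd(motu, species_by_genus[other[0]][0],
                    max(band[0], best_p - 0.5))
        best = max(r[4] for r in wfd_rows if r[0] == motu)
        gb(motu, targets[0], best_p - 0.1, best - 5.0)

    cols = ["qseqid", "sseqid", "pident", "qcovs", "bitscore", "lineage"]
    return (pd.DataFrame(wfd_rows, columns=cols),
            pd.DataFrame(gb_rows, columns=cols))


# ---------------------------------------------------------------------------
# morphology


def _build_morphology(cfg, rng, register: Register,
                      communities: dict[str, list[str]],
                      locations: list[str]
                      ) -> tuple[TaxonList, list[dict], list[dict]]:
    species_by_genus: dict[str, list[str]] = {}
    for t in register:
        if t.rank == "species" and t.in_register:
            species_by_genus.setdefault(t.ancestor_at("genus"), []).append(t.name)

    rows: list[tuple] = []
    swaps: list[dict] = []
    genus_only: list[dict] = []
    from .taxonomy import GROUPS as _G
    misses: list[dict] = []
    for loc in locations:
        for group in _G:
            for sp in communities[f"{loc}|{group}"]:
                ref = register.resolve(sp)
                name, rank = sp, "species"
                if rng.random() < cfg.morph_miss_rate:
                    misses.append({"location": loc, "group": group,
                                   "species": sp})
                    continue
                u = rng.random()
                if u < cfg.misid_rate:
                    genus = ref.ancestor_at("genus")
                    others = [s for s in species_by_genus.get(genus, [])
                              if s != sp]
                    if others:
                        name = others[int(rng.integers(len(others)))]
                        swaps.append({"location": loc, "group": group,
                                      "true": sp, "recorded": name})
                elif u < cfg.misid_rate + cfg.genus_only_rate:
                    name, rank = ref.ancestor_at("genus"), "genus"
                    genus_only.append({"location": loc, "group": group,
                                       "species": sp, "genus": name})
                rows.append((loc, group, name, rank,
                             1 + int(rng.poisson(5.0))))
    df = pd.DataFrame(rows, columns=["location", "group", "taxon", "rank",
                                     "count"])
    df = (df.groupby(["location", "group", "taxon", "rank"], as_index=False)
            ["count"].sum())
    return (TaxonList(df[["location", "group", "taxon", "rank", "count"]],
                      origin="morphology"), swaps, genus_only, misses)


# ---------------------------------------------------------------------------
# truth evaluation


def truth_evaluate(study: SimulatedStudy, result) -> dict:
    """Confront a :class:`~metasort.pipeline.PipelineResult` with the truth.

    Reports species-level recovery for sorted and pooled routes, false taxa
    (species-rank DNA entries absent from the location's true community),
    recall of injected congeneric swaps as putative misidentifications, and
    the category distribution of reference-coverage gaps.
    """
    truth = study.truth
    true_pairs: set[tuple[str, str]] = set()
    for key, com in truth.communities.items():
        loc, _ = key.split("|")
        true_pairs.update((loc, sp) for sp in com)
    failed = set(truth.forced_failures)
    dropped = set(truth.dropout_species)
    refdb = study.refdb_species

    def species_entries(lst) -> set[tuple[str, str]]:
        df = lst.entries
        sub = df[df["rank"] == "species"]
        return set(zip(sub["location"], sub["taxon"]))

    rec_sorted = species_entries(result.dna_sorted)
    rec_pooled = species_entries(result.dna_pooled)

    eligible_sorted = {
        (key.split("|")[0], sp)
        for key, com in truth.communities.items()
        for sp in com
        if sp in refdb and sp not in dropped
        and f"{key.split('|')[0]}_{key.split('|')[1]}" not in failed}
    eligible_pooled = {(loc, sp) for (loc, sp) in true_pairs
                       if sp in refdb and sp not in dropped
                       and f"{loc}_POOL" not in failed}

    out: dict = {
        "n_true_pairs": len(true_pairs),
        "recovered_sorted": len(rec_sorted & true_pairs),
        "recovered_pooled": len(rec_pooled & true_pairs),
        "false_taxa_sorted": sorted(rec_sorted - true_pairs),
        "false_taxa_pooled": sorted(rec_pooled - true_pairs),
        "recovery_sorted": (len(rec_sorted & eligible_sorted)
                            / len(eligible_sorted) if eligible_sorted else
                            float("nan")),
        "recovery_pooled": (len(rec_pooled & eligible_pooled)
                            / len(eligible_pooled) if eligible_pooled else
                            float("nan")),
    }

    # swap recall: both partners must have survived to the comparison
    morph_pairs = set(zip(result.morphology_excluded.entries["location"],
                          result.morphology_excluded.entries["taxon"]))
    e = result.entries_sorted
    misid = set(zip(e.loc[e["category"] == "putative_misid", "location"],
                    e.loc[e["category"] == "putative_misid", "taxon_morph"],
                    e.loc[e["category"] == "putative_misid", "taxon_dna"]))
    eligible_swaps = [s for s in truth.swaps
                      if (s["location"], s["recorded"]) in morph_pairs
                      and (s["location"], s["true"]) in rec_sorted
                      and (s["location"], s["recorded"]) not in rec_sorted
                      and (s["location"], s["true"]) not in morph_pairs]
    hit = [s for s in eligible_swaps
           if (s["location"], s["recorded"], s["true"]) in misid]
    out["eligible_swaps"] = len(eligible_swaps)
    out["swap_recall"] = (len(hit) / len(eligible_swaps)
                          if eligible_swaps else float("nan"))

    # where do reference-coverage gaps end up?
    uncovered = set(truth.uncovered_species)
    gap_rows = e[e["taxon_morph"].isin(uncovered)]
    out["uncovered_categories"] = (
        gap_rows["category"].value_counts().to_dict())
    return out


# ---------------------------------------------------------------------------
# sequence-level simulation (exercises the clustering kernel)

_BASES = np.array(list("ACGT"))


def simulate_reads(n_species: int = 5, reads_per_species: int = 20,
                   length: int = 316, substitution_rate: float = 0.005,
                   divergence: float = 0.08, seed: int = 0
                   ) -> tuple[list[str], dict[str, int]]:
    """Simulate COI-like reads: one random template per species (pairwise
    divergence well above the 2% clustering radius), each read a copy with
    independent substitution errors well below it. Returns the reads and the
    template -> species-index map."""
    rng = np.random.default_rng(seed)
    templates = []
    base = rng.integers(0, 4, size=length)
    for i in range(n_species):
        seq = base.copy()
        nmut = max(1, int(round(divergence * length)))
        pos = rng.choice(length, size=nmut, replace=False)
        seq[pos] = (seq[pos] + rng.integers(1, 4, size=nmut)) % 4
        templates.append(seq)
    reads: list[str] = []
    origin: dict[str, int] = {}
    for i, tpl in enumerate(templates):
        origin["".join(_BASES[tpl])] = i
        for _ in range(reads_per_species):
            seq = tpl.copy()
            nerr = rng.binomial(length, substitution_rate)
            if nerr:
                pos = rng.choice(length, size=nerr, replace=False)
                seq[pos] = (seq[pos] + rng.integers(1, 4, size=nerr)) % 4
            reads.append("".join(_BASES[seq]))
    return reads, origin
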