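"""Taxonomic backbone for metabarcoding identification pipelines.

A fixed five-level hierarchy (order > family > genus > species > subspecies)
underlies every identification step: name matching against a national species
register with synonym resolution, lowest-common-ancestor queries capped at a
maximum rank, and redundancy removal on taxon lists (dropping a higher-rank
entry when the list also contains a taxon nested inside it).

Intermediate ranks (tribe, subfamily, ...) are flattened at ingest; field
monitoring lists for freshwater macroinvertebrates are identified only to
these five levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

RANKS: tuple[str, ...] = ("order", "family", "genus", "species", "subspecies")
RANK_DEPTH: dict[str, int] = {r: i for i, r in enumerate(RANKS)}

#: Sorting groups used when bulk samples are pre-sorted before DNA extraction:
#: Annelida; Crustacea; Heteroptera+Coleoptera; Mollusca; Trichoptera+Odonata+
#: Ephemeroptera; and the rest (mostly Diptera).
GROUPS: tuple[str, ...] = ("ANNE", "CRUS", "HECO", "MOLL", "TOE", "REST")


class TaxonomyError(ValueError):
    """Raised for malformed registers, unknown taxa or invalid rank arguments."""


@dataclass(frozen=True)
class TaxonRef:
    """A resolved taxon: canonical name, rank, and full lineage from order down.

    ``lineage`` holds the ancestor names starting at order and ending at the
    taxon itself, so ``len(lineage) == RANK_DEPTH[rank] + 1``.
    """

    name: str
    rank: str
    lineage: tuple[str, ...]
    in_register: bool = True

    def __post_init__(self) -> None:
        if self.rank not in RANK_DEPTH:
            raise TaxonomyError(f"unknown rank {self.rank!r}")
        if len(self.lineage) != RANK_DEPTH[self.rank] + 1:
            raise TaxonomyError(
                f"lineage length {len(self.lineage)} inconsistent with rank "
                f"{self.rank!r} for {self.name!r}"
            )
        if self.lineage[-1] != self.name:
            raise TaxonomyError(f"lineage of {self.name!r} must end at itself")

    @property
    def depth(self) -> int:
        return RANK_DEPTH[self.rank]

    def ancestor_at(self, rank: str) -> Optional[str]:
        """Name of the ancestor at ``rank``, or None if shallower than self."""
        d = RANK_DEPTH[rank]
        if d > self.depth:
            return None
        return self.lineage[d]

    def is_strict_ancestor_of(self, other: "TaxonRef") -> bool:
        """True if self lies on ``other``'s lineage above ``other`` itself."""
        return (
            self.depth < other.depth
            and other.lineage[: self.depth + 1] == self.lineage
        )


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching a raw name against the register.

    Unmatched names are retained (``taxon is None``) rather than silently
    dropped, so they can be reported for manual review.
    """

    query: str
    taxon: Optional[TaxonRef]
    via: Optional[str] = None  # "exact" | "synonym" | "subspecies"

    @property
    def matched(self) -> bool:
        return self.taxon is not None


class Register:
    """A ranked species register with synonym links.

    Models a national checklist (e.g. a WFD species list): canonical taxa at
    order/family/genus/species rank, plus synonym rows pointing at canonical
    targets and subspecies rows collapsing onto their parent species.
    """

    def __init__(self) -> None:
        self._taxa: dict[str, TaxonRef] = {}
        self._synonyms: dict[str, str] = {}
        self._subspecies_parent: dict[str, str] = {}

    # -- construction -----------------------------------------------------

    def add(self, name: str, rank: str, parent: Optional[str] = None,
            in_register: bool = True) -> TaxonRef:
        if rank not in RANK_DEPTH:
            raise TaxonomyError(f"unknown rank {rank!r}")
        if rank == "order":
            lineage: tuple[str, ...] = (name,)
        else:
            if parent is None:
                raise TaxonomyError(f"{rank} {name!r} requires a parent")
            pref = self._taxa.get(parent)
            if pref is None:
                raise TaxonomyError(f"parent {parent!r} of {name!r} not loaded")
            if pref.depth != RANK_DEPTH[rank] - 1:
                raise TaxonomyError(
                    f"parent of {rank} {name!r} must be a "
                    f"{RANKS[RANK_DEPTH[rank] - 1]}, got {pref.rank}"
                )
            lineage = pref.lineage + (name,)
        ref = TaxonRef(name=name, rank=rank, lineage=lineage,
                       in_register=in_register)
        if rank == "subspecies":
            # Subspecies never stand on their own; they collapse to species.
            self._subspecies_parent[name] = parent  # type: ignore[arg-type]
        self._taxa[name] = ref
        return ref

    def add_synonym(self, alternative: str, canonical: str) -> None:
        target = self._taxa.get(canonical)
        if target is None:
            raise TaxonomyError(f"synonym target {canonical!r} not loaded")
        if not target.in_register:
            raise TaxonomyError(
                f"synonym target {canonical!r} must be a register member"
            )
        if alternative in self._taxa:
            raise TaxonomyError(f"{alternative!r} is already a canonical name")
        self._synonyms[alternative] = canonical

    # -- queries ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self._taxa)

    def __contains__(self, name: str) -> bool:
        return name in self._taxa or name in self._synonyms

    def __iter__(self) -> Iterator[TaxonRef]:
        return iter(self._taxa.values())

    def get(self, name: str) -> Optional[TaxonRef]:
        return self._taxa.get(name)

    def resolve(self, name: str) -> TaxonRef:
        ref = self._taxa.get(name)
        if ref is None:
            raise TaxonomyError(f"unknown taxon {name!r}")
        return ref

    @property
    def orders(self) -> frozenset[str]:
        """Order names in the register; defines the screening target set."""
        return frozenset(t.name for t in self._taxa.values()
                         if t.rank == "order" and t.in_register)

    def species_names(self, in_register_only: bool = True) -> frozenset[str]:
        return frozenset(
            t.name for t in self._taxa.values()
            if t.rank == "species" and (t.in_register or not in_register_only)
        )

    # -- name matching ----------------------------------------------------

    def match_name(self, raw_name: str) -> MatchResult:
        """Match a raw name to a canonical register taxon.

        Resolution order: exact canonical name; explicit subspecies row
        (collapsed to the parent species); synonym link; trinomial heuristic
        (``Genus epithet subsp`` collapses to the binomial when that binomial
        resolves). Unmatched names come back flagged, never dropped.
        """
        if not self._taxa:
            raise TaxonomyError("register is empty")
        raw_name = raw_name.strip()
        if not raw_name:
            raise TaxonomyError("empty query name")

        ref = self._taxa.get(raw_name)
        if ref is not None:
            if ref.rank == "subspecies":
                parent = self.resolve(self._subspecies_parent[ref.name])
                return MatchResult(raw_name, parent, via="subspecies")
            return MatchResult(raw_name, ref, via="exact")

        canonical = self._synonyms.get(raw_name)
        if canonical is not None:
            ref = self.resolve(canonical)
            if ref.rank == "subspecies":
                ref = self.resolve(self._subspecies_parent[ref.name])
            return MatchResult(raw_name, ref, via="synonym")

        tokens = raw_name.split()
        if len(tokens) >= 3:
            binomial = " ".join(tokens[:2])
            if binomial in self:
                inner = self.match_name(binomial)
                if inner.matched and inner.taxon.rank == "species":
                    return MatchResult(raw_name, inner.taxon, via="subspecies")

        return MatchResult(raw_name, None)

    # -- serialisation ----------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path) -> "Register":
        """Load from CSV with columns name, rank, parent, canonical_name,
        in_register. A non-empty canonical_name marks a synonym row."""
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        reg = cls()
        df = df.assign(_depth=df["rank"].map(RANK_DEPTH))
        if df["_depth"].isna().any():
            bad = df.loc[df["_depth"].isna(), "rank"].unique()
            raise TaxonomyError(f"unknown ranks in register file: {list(bad)}")
        synonyms = df[df["canonical_name"] != ""]
        canon = df[df["canonical_name"] == ""].sort_values("_depth", kind="stable")
        for r in canon.to_dict("records"):
            reg.add(r["name"], r["rank"], r["parent"] or None,
                    in_register=str(r["in_register"]).lower() in ("1", "true", "yes"))
        for r in synonyms.to_dict("records"):
            reg.add_synonym(r["name"], r["canonical_name"])
        return reg

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in sorted(self._taxa.values(), key=lambda t: (t.depth, t.name)):
            parent = t.lineage[-2] if t.depth > 0 else ""
            rows.append((t.name, t.rank, parent, "", t.in_register))
        for alt, canonical in sorted(self._synonyms.items()):
            rank = self.resolve(canonical).rank
            rows.append((alt, rank, "", canonical, True))
        return pd.DataFrame(
            rows, columns=["name", "rank", "parent", "canonical_name",
                           "in_register"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def lowest_common_ancestor(taxa: Iterable[TaxonRef],
                           max_rank: str = "genus") -> Optional[TaxonRef]:
    """Deepest lineage node shared by all ``taxa``, clipped at ``max_rank``.

    With the default genus cap a single species input yields its genus, never
    the species itself — the behaviour of top-percent LCA classifiers that
    refuse species-level calls from ambiguous reference hits. Returns None
    when the taxa do not even share an order.
    """
    taxa = list(taxa)
    if not taxa:
        raise TaxonomyError("LCA of an empty taxon set is undefined")
    if max_rank not in RANK_DEPTH:
        raise TaxonomyError(f"unknown rank {max_rank!r}")
    max_depth = min(RANK_DEPTH[max_rank], min(t.depth for t in taxa))
    shared: list[str] = []
    for d in range(max_depth + 1):
        names = {t.lineage[d] for t in taxa}
        if len(names) != 1:
            break
        shared.append(names.pop())
    if not shared:
        return None
    return TaxonRef(
        name=shared[-1],
        rank=RANKS[len(shared) - 1],
        lineage=tuple(shared),
        in_register=all(t.in_register for t in taxa),
    )


@dataclass
class TaxonList:
    """A taxon occurrence list: one row per (location, group, taxon).

    ``entries`` columns: location, group, taxon, rank, count. ``origin``
    records how the list was produced (morphology, dna_sorted, dna_pooled).
    """

    entries: pd.DataFrame
    origin: str = "morphology"

    COLUMNS = ("location", "group", "taxon", "rank", "count")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.entries.columns)
        if missing:
            raise TaxonomyError(f"taxon list missing columns {sorted(missing)}")
        self.entries = self.entries.loc[:, list(self.COLUMNS)].reset_index(drop=True)
        if (self.entries["count"] < 1).any():
            raise TaxonomyError("taxon list counts must be >= 1")
        dup = self.entries.duplicated(["location", "group", "taxon"])
        if dup.any():
            raise TaxonomyError("duplicate (location, group, taxon) entries")

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_csv(cls, path: str | Path, origin: str = "morphology") -> "TaxonList":
        df = pd.read_csv(path, dtype={"location": str, "group": str,
                                      "taxon": str, "rank": str})
        return cls(df, origin=origin)

    def to_csv(self, path: str | Path) -> None:
        self.entries.to_csv(path, index=False)

    def match_to_register(self, register: Register) -> "TaxonList":
        """Canonicalise all names via the register; unmatched rows keep their
        raw name and are flagged in an ``unmatched`` report column."""
        rows = []
        for row in self.entries.itertuples(index=False):
            m = register.match_name(row.taxon)
            if m.matched:
                rows.append((row.location, row.group, m.taxon.name,
                             m.taxon.rank, row.count, False))
            else:
                rows.append((row.location, row.group, row.taxon, row.rank,
                             row.count, True))
        df = pd.DataFrame(rows, columns=list(self.COLUMNS) + ["unmatched"])
        # canonicalisation can merge rows (synonym + canonical both present)
        df = (df.groupby(["location", "group", "taxon", "rank", "unmatched"],
                         as_index=False)["count"].sum()
                .loc[:, list(self.COLUMNS) + ["unmatched"]])
        out = TaxonList(df[list(self.COLUMNS)], origin=self.origin)
        out.entries["unmatched"] = df["unmatched"].to_numpy()
        return out


def remove_redundant(taxa: TaxonList, register: Register,
                     ranks_above: Optional[str] = None
                     ) -> tuple[TaxonList, pd.DataFrame]:
    """Drop entries whose taxon is a strict ancestor of another entry's taxon
    at the same location.

    Rationale: a genus-level identification alongside congeneric species-level
    identifications is either an uncertainty or a duplicate; keeping both
    would double count. Applied along the whole lineage (a family entry is
    removed when a contained genus or species is present).

    Returns the pruned list and the removed rows for reporting. ``ranks_above``
    restricts pruning to ancestors at or above that rank (e.g. ``"genus"``
    reproduces the narrow genus-vs-species variant).
    """
    df = taxa.entries
    refs = {name: register.resolve(name) for name in df["taxon"].unique()}
    min_depth = RANK_DEPTH[ranks_above] if ranks_above is not None else None
    drop_idx: list[int] = []
    for loc, sub in df.groupby("location"):
        local = [refs[n] for n in sub["taxon"]]
        for idx, row in zip(sub.index, sub.itertuples(index=False)):
            a = refs[row.taxon]
            if min_depth is not None and a.depth < min_depth:
                continue
            if any(a.is_strict_ancestor_of(b) for b in local):
                drop_idx.append(idx)
    removed = df.loc[drop_idx].copy()
    kept = df.drop(index=drop_idx).reset_index(drop=True)
    return TaxonList(kept, origin=taxa.origin), removed
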