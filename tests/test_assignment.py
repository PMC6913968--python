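"""Direct-hit resolution rules, genus-capped LCA and contaminant screening."""

import pandas as pd
import pytest

from metasort import (AssignConfig, ResolutionConfig, assign_all, assign_motu,
                      find_direct_hits, lca_assign, resolve_direct,
                      screen_contaminants)
from metasort.assignment import aggregate_to_locations, results_frame

COLS = ["qseqid", "sseqid", "pident", "qcovs", "bitscore", "lineage"]


def hits(rows):
    return pd.DataFrame(rows, columns=COLS)


LIN = {
    "Asellus aquaticus": "Isopoda/Asellidae/Asellus/Asellus aquaticus",
    "Asellus meridianus": "Isopoda/Asellidae/Asellus/Asellus meridianus",
    "Asellus": "Isopoda/Asellidae/Asellus",
    "Proasellus coxalis": "Isopoda/Asellidae/Proasellus/Proasellus coxalis",
    "Gammarus pulex": "Amphipoda/Gammaridae/Gammarus/Gammarus pulex",
    "Gammarus exoticus": "Amphipoda/Gammaridae/Gammarus/Gammarus exoticus",
    "Rivulogammarus pulex": "Amphipoda/Gammaridae/Gammarus/Rivulogammarus pulex",
    "Homo sapiens": "Primates/Hominidae/Homo/Homo sapiens",
}


class TestDirectHits:
    def test_identity_boundary_is_strictly_above_98(self):
        h = hits([("m1", "r1", 98.0, 100.0, 580, LIN["Asellus aquaticus"]),
                  ("m1", "r2", 99.1, 100.0, 590, LIN["Gammarus pulex"])])
        assert find_direct_hits(h) == ["Gammarus pulex"]

    def test_full_coverage_required(self):
        h = hits([("m1", "r1", 99.5, 99.0, 580, LIN["Asellus aquaticus"])])
        assert find_direct_hits(h) == []

    def test_matches_predicate_oracle(self, rng):
        rows = [("m1", f"r{i}", float(rng.uniform(90, 100)),
                 float(rng.choice([80.0, 100.0])), 500.0,
                 LIN["Gammarus pulex"] + str(i))
                for i in range(200)]
        h = hits(rows)
        got = set(find_direct_hits(h))
        expect = {r[5].split("/")[-1] for r in rows
                  if r[2] > 98.0 and r[3] >= 100.0}
        assert got == expect


class TestResolveDirect:
    def test_rule1_drops_species_outside_register(self, toy_register):
        taxa, rules = resolve_direct(
            ["Asellus aquaticus", "Gammarus exoticus"], hits([]),
            toy_register)
        assert [t.name for t in taxa] == ["Asellus aquaticus"]
        assert rules == [1]

    def test_rule2_and_3_resolve_synonyms_and_subspecies(self, toy_register):
        taxa, rules = resolve_direct(
            ["Rivulogammarus pulex", "Gammarus pulex occidentalis"],
            hits([]), toy_register)
        assert [t.name for t in taxa] == ["Gammarus pulex"]
        assert set(rules) == {2, 3}

    def test_rule4_species_beats_congeneric_genus_entry(self, toy_register):
        taxa, rules = resolve_direct(
            ["Asellus", "Asellus aquaticus"], hits([]), toy_register)
        assert [t.name for t in taxa] == ["Asellus aquaticus"]
        assert 4 in rules

    def test_rule5_blocklist_removes_curated_names(self, toy_register):
        taxa, rules = resolve_direct(
            ["Asellus aquaticus", "Gammarus pulex"], hits([]), toy_register,
            ResolutionConfig(blocklist=frozenset({"Gammarus pulex"})))
        assert [t.name for t in taxa] == ["Asellus aquaticus"]
        assert 5 in rules

    @pytest.mark.parametrize("margin,expected", [(1.0, 1), (2.0, 2)])
    def test_rule6_margin_on_best_identities(self, toy_register, margin,
                                             expected):
        h = hits([("m1", "r1", 99.8, 100.0, 590, LIN["Asellus aquaticus"]),
                  ("m1", "r2", 98.4, 100.0, 575, LIN["Asellus meridianus"])])
        taxa, rules = resolve_direct(
            ["Asellus aquaticus", "Asellus meridianus"], h, toy_register,
            ResolutionConfig(consistency_margin=margin))
        assert len(taxa) == expected
        if expected == 1:
            assert taxa[0].name == "Asellus aquaticus" and 6 in rules
        else:
            assert 7 in rules     # unresolved complex keeps all


class TestLCA:
    def test_top_percent_window_restricts_candidates(self, toy_register):
        h = hits([("m1", "a", 95.0, 100.0, 400,
                   LIN["Asellus aquaticus"]),
                  ("m1", "b", 94.0, 100.0, 392,
                   LIN["Asellus meridianus"]),
                  ("m1", "c", 88.0, 100.0, 310,
                   LIN["Gammarus pulex"])])
        lca = lca_assign(h, AssignConfig(), toy_register)
        assert lca.name == "Asellus" and lca.rank == "genus"

    def test_bitscore_must_strictly_exceed_170(self, toy_register):
        for score, ok in ((169.0, False), (170.0, False), (171.0, True)):
            h = hits([("m1", "a", 95.0, 100.0, score,
                       LIN["Asellus aquaticus"])])
            got = lca_assign(h, AssignConfig(), toy_register)
            assert (got is not None) is ok

    def test_single_species_capped_at_genus(self, toy_register):
        h = hits([("m1", "a", 97.0, 100.0, 500, LIN["Asellus aquaticus"])])
        lca = lca_assign(h, AssignConfig(), toy_register)
        assert lca.name == "Asellus" and lca.rank == "genus"

    def test_min_identity_and_coverage(self, toy_register):
        h = hits([("m1", "a", 79.9, 100.0, 500, LIN["Asellus aquaticus"]),
                  ("m1", "b", 90.0, 79.0, 500, LIN["Asellus meridianus"])])
        assert lca_assign(h, AssignConfig(), toy_register) is None


class TestScreening:
    def test_human_hit_outscoring_curated_hit_discards(self, toy_register):
        wfd = hits([("m1", "a", 82.0, 90.0, 300, LIN["Asellus aquaticus"])])
        gb = hits([("m1", "g", 99.5, 100.0, 580, LIN["Homo sapiens"])])
        keep, reason = screen_contaminants(wfd, gb, toy_register)
        assert not keep and "Homo sapiens" in reason

    def test_empty_genbank_keeps(self, toy_register):
        wfd = hits([("m1", "a", 99.0, 100.0, 580, LIN["Asellus aquaticus"])])
        keep, _ = screen_contaminants(wfd, hits([]), toy_register)
        assert keep

    def test_target_order_survives_even_if_outscored(self, toy_register):
        wfd = hits([("m1", "a", 98.5, 100.0, 560, LIN["Asellus aquaticus"])])
        gb = hits([("m1", "g", 99.0, 100.0, 575, LIN["Asellus meridianus"])])
        keep, _ = screen_contaminants(wfd, gb, toy_register)
        assert keep

    def test_all_spiked_contaminants_discarded_no_targets_lost(self, study,
                                                               result):
        kinds = study.truth.motu_kind
        by_motu = {r.motu: r for r in result.assignments}
        for motu, r in by_motu.items():
            if kinds[motu] in ("contaminant", "aic"):
                assert r.method == "discarded"
            if kinds[motu] == "haplotype" and r.method == "discarded":
                # target MOTUs may only be discarded for lack of resolution,
                # never as non-target contaminants
                assert not (r.reason or "").startswith("non-target")


class TestAssignAll:
    def _table(self):
        counts = pd.DataFrame({"S1": {"m1": 100, "m2": 50, "m3": 10}})
        reps = pd.DataFrame([("S1", "S1", "L1", "CRUS", 0, False)],
                            columns=["id", "sample", "location", "group",
                                     "replicate", "is_control"]).set_index("id")
        return counts, reps

    def test_conspecific_motus_aggregate_without_double_counting(
            self, toy_register):
        counts, reps = self._table()
        wfd = hits([("m1", "a", 99.5, 100.0, 585, LIN["Asellus aquaticus"]),
                    ("m2", "b", 99.0, 100.0, 580, LIN["Asellus aquaticus"]),
                    ("m3", "c", 91.0, 100.0, 420, LIN["Gammarus pulex"])])
        results, agg = assign_all(wfd, hits([]), counts, reps, toy_register)
        asellus = agg[agg["taxon"] == "Asellus aquaticus"]
        assert len(asellus) == 1 and int(asellus["count"].iloc[0]) == 150
        methods = {r.motu: r.method for r in results}
        assert methods == {"m1": "direct", "m2": "direct", "m3": "lca"}

    def test_motu_without_hits_is_unidentified(self, toy_register):
        counts, reps = self._table()
        wfd = hits([("m1", "a", 99.5, 100.0, 585, LIN["Asellus aquaticus"])])
        results, agg = assign_all(wfd, hits([]), counts, reps, toy_register)
        by = {r.motu: r for r in results}
        assert by["m2"].method == "discarded" and by["m2"].reason == "no hits"
        assert set(agg["taxon"]) == {"Asellus aquaticus"}

    def test_direct_and_lca_paths_are_mutually_exclusive(self, result):
        for r in result.assignments:
            assert r.method in ("direct", "lca", "discarded")
            if r.method == "lca":
                assert r.taxon.depth <= 2          # never deeper than genus
            if r.method == "direct":
                assert all(t.rank == "species" for t in r.taxa)

    def test_species_with_good_reference_recovered_at_species_rank(
            self, noise_free_study, noise_free_result):
        """With full reference coverage every true species is recovered at
        species rank in the sorted route."""
        truth = noise_free_study.truth
        lst = noise_free_result.dna_sorted.entries
        got = set(zip(lst[lst["rank"] == "species"]["location"],
                      lst[lst["rank"] == "species"]["taxon"]))
        expect = {(key.split("|")[0], sp)
                  for key, com in truth.communities.items() for sp in com}
        assert expect <= got

    def test_results_frame_shape(self, result):
        df = results_frame(result.assignments)
        assert set(df.columns) == {"motu", "method", "taxon", "rank",
                                   "rules", "reads", "reason"}
        assert len(df) == len(result.assignments)
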