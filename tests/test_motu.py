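"""Sequence QC, contamination threshold, abundance filtering, rarefaction."""

import numpy as np
import pandas as pd
import pytest

from tests.helpers import make_table
from metasort import (FilterConfig, QCConfig,
                      determine_contamination_threshold, dereplicate,
                      discard_and_combine, filter_by_length,
                      filter_low_abundance, greedy_cluster, pairwise_identity,
                      rarefy, run_filtering)
from metasort.motu import MotuError
from metasort.simulate import simulate_reads


class TestLengthFilter:
    def test_window_is_inclusive_at_both_bounds(self):
        seqs = ["A" * n for n in (312, 313, 316, 319, 320)]
        assert [len(s) for s in filter_by_length(seqs)] == [313, 316, 319]

    def test_empty_input(self):
        assert filter_by_length([]) == []

    def test_random_lengths_match_window_oracle(self, rng):
        lengths = rng.integers(300, 331, size=1000)
        seqs = ["T" * int(n) for n in lengths]
        kept = filter_by_length(seqs)
        assert len(kept) == int(((lengths >= 313) & (lengths <= 319)).sum())


class TestDereplicate:
    def test_singletons_dropped_at_min_abundance_two(self):
        assert dereplicate(["AAA", "AAA", "CCC"]) == [("AAA", 2)]

    def test_all_unique_input_yields_nothing(self):
        assert dereplicate(["AAA", "CCC", "GGG"]) == []

    def test_matches_counting_oracle_with_stable_order(self, rng):
        alphabet = ["A" * 3, "C" * 3, "G" * 3, "T" * 3, "ACG"]
        draws = [alphabet[i] for i in rng.integers(0, 5, size=200)]
        got = dereplicate(draws, QCConfig(min_derep_abundance=1))
        from collections import Counter
        counts = Counter(draws)
        assert dict(got) == dict(counts)
        abundances = [n for _, n in got]
        assert abundances == sorted(abundances, reverse=True)


class TestClustering:
    def test_identity_is_matches_over_alignment_length(self, rng):
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 316))
        b = list(a)
        pos = rng.choice(316, size=10, replace=False)
        for p in pos:
            b[p] = "ACGT"[("ACGT".index(b[p]) + 1) % 4]
        assert pairwise_identity(a, "".join(b)) == pytest.approx(306 / 316)
        assert pairwise_identity(a, a) == 1.0

    def test_two_identical_sequences_one_motu(self):
        clusters = greedy_cluster([("ACGT" * 79, 5), ("ACGT" * 79, 3)])
        assert len(clusters) == 1 and clusters[0].abundance == 8

    def test_ten_differences_split_at_98_percent(self, rng):
        a = "".join("ACGT"[i] for i in rng.integers(0, 4, 316))
        b = list(a)
        for p in rng.choice(316, size=10, replace=False):
            b[p] = "ACGT"[("ACGT".index(b[p]) + 1) % 4]
        clusters = greedy_cluster([(a, 10), ("".join(b), 5)])
        assert len(clusters) == 2

    def test_matches_bruteforce_greedy_with_hamming_identity(self):
        """Substitution-only reads: an independent greedy implementation
        using Hamming identity must produce the same clustering."""
        reads, _ = simulate_reads(n_species=4, reads_per_species=6,
                                  substitution_rate=0.004, seed=3)
        derep = dereplicate(reads, QCConfig(min_derep_abundance=1))
        got = greedy_cluster(derep)

        centroids: list[str] = []
        assign = []
        for seq, _ in derep:
            for i, c in enumerate(centroids):
                ham = sum(x != y for x, y in zip(seq, c))
                if 1 - ham / len(seq) >= 0.98:
                    assign.append(i)
                    break
            else:
                centroids.append(seq)
                assign.append(len(centroids) - 1)
        assert len(got) == len(centroids)
        assert [c.centroid for c in got] == centroids

    def test_cluster_count_nonincreasing_as_identity_relaxes(self):
        reads, _ = simulate_reads(n_species=5, reads_per_species=4,
                                  substitution_rate=0.01, seed=9)
        derep = dereplicate(reads, QCConfig(min_derep_abundance=1))
        counts = [len(greedy_cluster(derep, QCConfig(cluster_identity=t)))
                  for t in (0.995, 0.98, 0.95, 0.90)]
        assert counts == sorted(counts, reverse=True)


class TestContaminationThreshold:
    def test_clean_table_gives_zero(self):
        t = make_table({"S1_r1": {"m1": 100, "AIC": 0},
                        "C1_r1": {"m1": 0, "AIC": 500}},
                       control_reps=["C1_r1"])
        assert determine_contamination_threshold(t) == 0.0

    def test_single_offender_arithmetic(self):
        t = make_table({"S1_r1": {"m1": 39991, "AIC": 9},
                        "C1_r1": {"m1": 0, "AIC": 500}},
                       control_reps=["C1_r1"])
        assert determine_contamination_threshold(t) == pytest.approx(
            9 / 40000)

    def test_requires_a_control_replicate(self):
        t = make_table({"S1_r1": {"m1": 10, "AIC": 0}})
        with pytest.raises(MotuError):
            determine_contamination_threshold(t)

    def test_matches_max_scan_oracle_under_random_injections(self, rng):
        for _ in range(25):
            counts = {}
            for s in range(4):
                rep = f"S{s}_r1"
                counts[rep] = {f"m{i}": int(rng.integers(0, 5000))
                               for i in range(6)}
                counts[rep]["AIC"] = int(rng.integers(0, 12))
            counts["C1_r1"] = {f"m{i}": int(rng.integers(0, 4))
                               for i in range(6)}
            counts["C1_r1"]["AIC"] = 20000
            t = make_table(counts, control_reps=["C1_r1"])
            got = determine_contamination_threshold(t)
            # oracle: scan every offending cell's relative abundance
            offenders = []
            totals = t.counts.sum(axis=0)
            for rep in t.counts.columns:
                for m in t.counts.index:
                    n = t.counts.loc[m, rep]
                    if n == 0:
                        continue
                    off = (m == "AIC") != (rep == "C1_r1")
                    if off:
                        offenders.append(n / totals[rep])
            assert got == pytest.approx(max(offenders, default=0.0))
            # applying the derived threshold clears all contamination
            filtered = filter_low_abundance(
                t, FilterConfig(motu_rel_abundance_threshold=got))
            assert filtered.counts.loc["AIC",
                                       [c for c in t.counts.columns
                                        if c != "C1_r1"]].sum() == 0


class TestAbundanceFilter:
    def test_boundary_at_exactly_threshold_removed(self):
        t = make_table({"S1_r1": {"m1": 39979, "m2": 10, "m3": 11,
                                  "AIC": 0}},
                       control_reps=[])
        f = filter_low_abundance(t)   # default 0.00025 on total 40,000
        assert f.counts.loc["m2", "S1_r1"] == 0      # exactly 0.025%
        assert f.counts.loc["m3", "S1_r1"] == 11     # strictly above

    def test_zero_threshold_removes_nothing(self):
        t = make_table({"S1_r1": {"m1": 5, "m2": 1, "AIC": 0}})
        f = filter_low_abundance(
            t, FilterConfig(motu_rel_abundance_threshold=0.0))
        assert f.counts.equals(t.counts)

    def test_matches_elementwise_oracle_on_prefilter_totals(self, rng):
        for _ in range(20):
            counts = {f"S{s}_r1": {f"m{i}": int(rng.integers(0, 2000))
                                   for i in range(8)}
                      for s in range(3)}
            t = make_table({r: {**c, "AIC": 0} for r, c in counts.items()})
            thr = float(rng.uniform(0, 0.02))
            f = filter_low_abundance(
                t, FilterConfig(motu_rel_abundance_threshold=thr))
            totals = t.counts.sum(axis=0)
            for rep in t.counts.columns:
                for m in t.counts.index:
                    n = int(t.counts.loc[m, rep])
                    keep = totals[rep] > 0 and n / totals[rep] > thr
                    assert int(f.counts.loc[m, rep]) == (n if keep else 0)
            assert (f.counts.to_numpy() <= t.counts.to_numpy()).all()


class TestDiscardAndCombine:
    def test_additive_merge_unions_motus(self):
        t = make_table({"S1_r1": {"m1": 4100, "m2": 5, "m3": 0, "AIC": 0},
                        "S1_r2": {"m1": 4050, "m2": 0, "m3": 7, "AIC": 0}})
        combined, failed = discard_and_combine(t)
        assert failed.empty
        col = combined.counts["S1"]
        assert col["m1"] == 8150 and col["m2"] == 5 and col["m3"] == 7

    def test_depth_boundary_is_strictly_fewer_than(self):
        t = make_table({"S1_r1": {"m1": 3999, "AIC": 0},
                        "S1_r2": {"m1": 4000, "AIC": 0}})
        combined, failed = discard_and_combine(t)
        assert combined.counts.loc["m1", "S1"] == 4000   # r1 dropped
        assert failed.empty

    def test_sample_fails_when_all_replicates_below_cutoff(self):
        t = make_table({"S1_r1": {"m1": 900, "AIC": 0},
                        "S1_r2": {"m1": 1200, "AIC": 0},
                        "S2_r1": {"m1": 9000, "AIC": 0}})
        combined, failed = discard_and_combine(t)
        assert list(failed["sample"]) == ["S1"]
        assert list(combined.counts.columns) == ["S2"]

    def test_merging_conserves_surviving_reads(self, rng):
        counts = {f"S{s}_r{r}": {f"m{i}": int(rng.integers(0, 9000))
                                 for i in range(5)}
                  for s in range(3) for r in (1, 2)}
        t = make_table({k: {**v, "AIC": 0} for k, v in counts.items()})
        combined, failed = discard_and_combine(t)
        totals = t.counts.sum(axis=0)
        surviving = totals[totals >= 4000].sum()
        assert combined.counts.to_numpy().sum() == surviving


class TestRarefy:
    def test_depth_equal_to_total_is_identity(self):
        c = pd.Series({"a": 3, "b": 1})
        assert rarefy(c, 4, 0).equals(c)

    def test_depth_above_total_is_an_error(self):
        with pytest.raises(MotuError):
            rarefy(pd.Series({"a": 3}), 10, 0)

    def test_hypergeometric_expectation(self):
        c = pd.Series({"a": 3, "b": 1})
        means = np.mean([rarefy(c, 2, seed)["a"] for seed in range(2000)])
        assert means == pytest.approx(1.5, abs=0.05)

    def test_richness_never_increases(self, rng):
        c = pd.Series(rng.integers(0, 50, size=30))
        for seed in range(10):
            sub = rarefy(c, 100, seed)
            assert (sub <= c).all()
            assert (sub > 0).sum() <= (c > 0).sum()
            assert sub.sum() == 100


class TestPipelineOrder:
    def test_derived_threshold_clears_aic_outside_controls(self, study):
        combined, failed, t = run_filtering(study.table)
        assert t > 0
        reps = combined.replicates
        regular = [c for c in combined.counts.columns
                   if not reps.loc[c, "is_control"]]
        aic = combined.counts.loc[combined.motus["is_control_sequence"],
                                  regular]
        assert aic.to_numpy().sum() == 0

    def test_forced_failures_end_up_in_failed_registry(self, study):
        _, failed, _ = run_filtering(study.table)
        assert set(study.truth.forced_failures) == set(failed["sample"])
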