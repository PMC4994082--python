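"""Half-max allele calling, replicate resolution, and encoding."""

import numpy as np
import pytest

import msatpipe as mp
from msatpipe.tally import SeqTally

from conftest import truth_pairs


class TestSelectCandidates:
    def test_half_max_threshold(self):
        cands = mp.select_candidates({"a": 120, "b": 70, "c": 59})
        assert [d for _, d in cands] == [120, 70]  # 59 <= 60 excluded

    def test_single_sequence_homozygote(self):
        cands = mp.select_candidates({"a": 200})
        assert cands == [("a", 200)]
        assert mp.resolve_genotype(cands, "depth", np.random.default_rng(0)) == ("a", "a")

    def test_empty_tally_is_missing_not_error(self):
        assert mp.select_candidates({}) == []

    def test_matches_brute_force_predicate(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            depths = {f"s{i}": int(rng.integers(1, 300)) for i in range(rng.integers(1, 8))}
            cands = dict(mp.select_candidates(depths))
            top = max(depths.values())
            expected = {s: d for s, d in depths.items() if d > top / 2}
            assert cands == expected

    def test_top_ties_all_retained(self):
        cands = mp.select_candidates({"a": 100, "b": 100, "c": 49})
        assert {s for s, _ in cands} == {"a", "b"}


class TestResolveGenotype:
    def test_depth_strategy_next_highest(self):
        cands = [("x", 100), ("y", 80), ("z", 60)]
        assert mp.resolve_genotype(cands, "depth", np.random.default_rng(0)) == ("x", "y")

    def test_depth_strategy_tied_second_random_but_seeded(self):
        cands = [("x", 100), ("y", 80), ("z", 80)]
        picks = {mp.resolve_genotype(cands, "depth", np.random.default_rng(s))[1] for s in range(20)}
        assert picks == {"y", "z"}
        a = mp.resolve_genotype(cands, "depth", np.random.default_rng(5))
        b = mp.resolve_genotype(cands, "depth", np.random.default_rng(5))
        assert a == b

    def test_random_strategy_uniform_over_alternatives(self):
        cands = [("x", 100), ("y", 80), ("z", 60)]
        rng = np.random.default_rng(9)
        picks = [mp.resolve_genotype(cands, "random", rng)[1] for _ in range(10_000)]
        frac_y = picks.count("y") / len(picks)
        assert abs(frac_y - 0.5) < 0.02

    def test_resolved_subset_of_candidates(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            depths = {f"s{i}": int(rng.integers(1, 50)) for i in range(rng.integers(1, 6))}
            cands = mp.select_candidates(depths)
            for strategy in ("depth", "random"):
                pair = mp.resolve_genotype(cands, strategy, rng)
                names = {s for s, _ in cands}
                assert set(pair) <= names
                assert pair[0] in {s for s, d in cands if d == cands[0][1]}

    def test_unknown_strategy_errors(self):
        with pytest.raises(ValueError):
            mp.resolve_genotype([("a", 1)], "best", np.random.default_rng(0))


class TestReplicates:
    def test_no_multi_candidate_calls_identical_replicates(self):
        t = SeqTally(
            {
                ("S1", "c00", "locA"): {"AA": 30, "CC": 25},
                ("S1", "c01", "locA"): {"AA": 40},
            }
        )
        reps = mp.generate_replicate_datasets(t, k=5, seed=0)
        first = {k: v.resolved for k, v in reps[0].items()}
        for rep in reps[1:]:
            assert {k: v.resolved for k, v in rep.items()} == first

    def test_multi_candidate_calls_differ_somewhere(self):
        t = SeqTally(
            {
                ("S1", f"c{i:02d}", "locA"): {"AA": 30, "CC": 25, "GG": 20}
                for i in range(20)
            }
        )
        reps = mp.generate_replicate_datasets(t, k=10, seed=1)
        resolved = [tuple(sorted(v.resolved for v in rep.values())) for rep in reps]
        assert len(set(resolved)) > 1

    def test_fixed_seed_reproducible(self):
        t = SeqTally(
            {("S1", "c00", "locA"): {"AA": 30, "CC": 25, "GG": 20}}
        )
        a = mp.generate_replicate_datasets(t, k=3, seed=7)
        b = mp.generate_replicate_datasets(t, k=3, seed=7)
        assert [{k: v.resolved for k, v in rep.items()} for rep in a] == [
            {k: v.resolved for k, v in rep.items()} for rep in b
        ]


class TestEncoding:
    def test_same_length_snp_merges_only_in_length_mode(self, small_loci):
        locus = small_loci[0]
        reps = locus.repeat_range[0] + 1
        seq_a = mp.build_allele_sequence(locus, reps)
        seq_b = mp.build_allele_sequence(locus, reps, variant=1)
        assert len(seq_a) == len(seq_b) and seq_a != seq_b
        t = SeqTally(
            {
                ("S1", "c00", locus.name): {seq_a: 30, seq_b: 25},
                ("S1", "c01", locus.name): {seq_a: 30, seq_b: 25},
            }
        )
        calls = mp.call_genotypes(t, "depth", np.random.default_rng(0))
        by_len = mp.encode_alleles(calls, "length")
        by_id = mp.encode_alleles(calls, "unique_id")
        assert by_len.n_alleles(locus.name) == 1
        assert by_id.n_alleles(locus.name) == 2
        # length mode sees a homozygote where unique-ID sees a heterozygote
        assert by_len.alleles[0, 0, 0] == by_len.alleles[0, 0, 1]
        assert by_id.alleles[0, 0, 0] != by_id.alleles[0, 0, 1]

    def test_homozygote_same_label_in_both_modes(self, small_loci):
        locus = small_loci[0]
        seq = mp.build_allele_sequence(locus, locus.repeat_range[0])
        t = SeqTally({("S1", "c00", locus.name): {seq: 30}})
        calls = mp.call_genotypes(t, "depth", np.random.default_rng(0))
        for mode in ("length", "unique_id"):
            gm = mp.encode_alleles(calls, mode)
            assert gm.alleles[0, 0, 0] == gm.alleles[0, 0, 1]

    def test_unique_id_alleles_at_least_length_alleles(self, noise_free_small):
        calls = noise_free_small["calls"]
        by_len = mp.encode_alleles(calls, "length")
        by_id = mp.encode_alleles(calls, "unique_id")
        for locus in by_len.loci:
            assert by_id.n_alleles(locus) >= by_len.n_alleles(locus)

    def test_noise_free_calls_equal_truth_in_both_encodings(self, noise_free_small):
        """End-to-end genotype recovery on the compact noise-free library."""
        truth = noise_free_small["truth"]
        calls = noise_free_small["calls"]
        pairs = truth_pairs(truth)
        assert len(calls) == len(pairs)
        for key, call in calls.items():
            assert tuple(sorted(call.resolved)) == pairs[key]
        # length-encoded matrix equals length-encoded truth
        frame = truth.to_frame()
        by_len = mp.encode_alleles(calls, "length")
        motif_len = {l.name: len(l.motif) for l in truth.loci}
        for r in frame.itertuples():
            i = by_len.individuals.index(f"{r.site}_{r.colony}")
            l = by_len.loci.index(r.locus)
            labels = by_len.allele_labels[r.locus]
            called = sorted(labels[x] for x in by_len.alleles[i, l])
            expected = sorted(
                motif_len[r.locus] * x for x in (r.allele1_repeats, r.allele2_repeats)
            )
            assert called == expected
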