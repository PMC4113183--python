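"""Seed alignment, hierarchical library assignment, novel-candidate filter."""
from __future__ import annotations

import itertools

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirdiffreg.annotate import (
    ArmPair,
    ClusterRead,
    ReadCluster,
    ReferenceLibrary,
    annotate_matrix,
    cluster_reads,
    novel_candidate_filter,
    seed_align,
)

MIR = "UGUAAACAUCCCCGACUGGAAG"  # 22 nt, canonical-style consensus


def brute_force_seed_align(read, consensus, budget, offsets, seed_length=20):
    """Independent all-offsets Hamming oracle."""
    seed = read[: min(seed_length, len(read))]
    best = None
    for o in offsets:
        mm = 0
        for i in range(len(seed)):
            j = o + i
            if j < 0 or j >= len(consensus) or consensus[j] != seed[i]:
                mm += 1
        best = mm if best is None else min(best, mm)
    return best if best is not None and best <= budget else None


class TestSeedAlign:
    def test_exact_match(self):
        assert seed_align(MIR, MIR, budget=0) == 0

    def test_nta_outside_seed_costs_nothing(self):
        assert seed_align(MIR + "UU", MIR, budget=0) == 0

    def test_mismatch_budgets(self):
        read = list(MIR)
        read[2] = "A" if read[2] != "A" else "C"
        read[8] = "A" if read[8] != "A" else "C"
        read = "".join(read)
        assert seed_align(read, MIR, budget=1) is None
        assert seed_align(read, MIR, budget=2) == 2

    def test_offset_within_tolerance(self):
        # isomiR starting 2 nt inside the consensus 5' end
        assert seed_align(MIR[2:], MIR, budget=0, max_offset=2) == 0
        assert seed_align(MIR[2:], MIR, budget=0, max_offset=1) is None

    def test_mismatches_beyond_twentieth_nt_ignored(self):
        read = MIR[:20] + "AA"  # corrupt positions 21-22
        assert seed_align(read, MIR, budget=0) == 0

    def test_empty_consensus_raises(self):
        with pytest.raises(ValueError):
            seed_align(MIR, "", budget=1)

    def test_exhaustive_small_instances_match_oracle(self):
        # every 16-nt read over a 2-letter alphabet vs a fixed 25-nt consensus
        consensus = "ACGUACGUACGUACGUACGUACGUA"
        for bits in itertools.product("AC", repeat=8):
            read = "".join(bits) * 2  # 16 nt
            got = seed_align(read, consensus, budget=3, max_offset=None, seed_length=20)
            want = brute_force_seed_align(read, consensus, 3, range(-15, 25))
            assert got == want

    @settings(max_examples=300, deadline=None)
    @given(
        read=st.text(alphabet="ACGU", min_size=16, max_size=25),
        consensus=st.text(alphabet="ACGU", min_size=10, max_size=40),
        budget=st.integers(min_value=0, max_value=3),
    )
    def test_random_instances_match_oracle(self, read, consensus, budget):
        got = seed_align(read, consensus, budget, max_offset=None)
        want = brute_force_seed_align(
            read, consensus, budget, range(-len(read[:20]) + 1, len(consensus))
        )
        assert got == want


def _matrix(rows: dict[str, list[int]], pools=("p1", "p2")) -> pd.DataFrame:
    return pd.DataFrame(rows, index=list(pools)).T


class TestAnnotateMatrix:
    def make_libs(self):
        lib1 = ReferenceLibrary(
            rank=1, name="known-mirna",
            entries=(("mir-a", MIR), ("mir-b", "CCCCAGGGUUUUACGUACGUAC")),
            mismatch_budget=1,
        )
        lib2 = ReferenceLibrary(
            rank=2, name="trna",
            entries=(("trna-x", MIR),),  # deliberately also matches mir-a reads
            mismatch_budget=2,
        )
        return [lib1, lib2]

    def test_precedence_first_library_wins(self):
        m = _matrix({MIR: [3, 0]})
        res = annotate_matrix(m, self.make_libs())
        assert res.annotations.loc[MIR, "identifier"] == "mir-a"
        assert res.annotations.loc[MIR, "library"] == "known-mirna"

    def test_isomir_counts_add_up(self):
        isomir = MIR + "U"
        m = _matrix({MIR: [3, 0], isomir: [4, 2]})
        res = annotate_matrix(m, self.make_libs())
        assert res.identifier_matrix.loc["mir-a", "p1"] == 7
        assert res.identifier_matrix.loc["mir-a", "p2"] == 2

    def test_unassigned_kept_unnamed(self):
        stranger = "GGGGUUUUCCCCAAAAGGGG"
        m = _matrix({MIR: [1, 0], stranger: [5, 5]})
        res = annotate_matrix(m, self.make_libs())
        assert res.annotations.loc[stranger, "identifier"] is None
        assert stranger in res.reads_matrix.index

    def test_counts_conserved_through_annotation(self):
        stranger = "GGGGUUUUCCCCAAAAGGGG"
        m = _matrix({MIR: [3, 1], MIR + "UU": [2, 2], stranger: [5, 5]})
        res = annotate_matrix(m, self.make_libs())
        unassigned = res.annotations["identifier"].isna()
        total = res.identifier_matrix.sum().sum() + m.loc[unassigned[unassigned].index].sum().sum()
        assert total == m.sum().sum()

    def test_rank_permutation_changes_only_multi_hits(self):
        m = _matrix({MIR: [3, 0]})
        libs = self.make_libs()
        res_fwd = annotate_matrix(m, libs)
        flipped = [
            ReferenceLibrary(rank=1, name=libs[1].name, entries=libs[1].entries,
                             mismatch_budget=libs[1].mismatch_budget),
            ReferenceLibrary(rank=2, name=libs[0].name, entries=libs[0].entries,
                             mismatch_budget=libs[0].mismatch_budget),
        ]
        res_rev = annotate_matrix(m, flipped)
        assert res_fwd.annotations.loc[MIR, "identifier"] == "mir-a"
        assert res_rev.annotations.loc[MIR, "identifier"] == "trna-x"

    def test_intra_library_tie_lexicographic(self):
        lib = ReferenceLibrary(
            rank=1, name="dup", entries=(("mir-z", MIR), ("mir-a2", MIR)), mismatch_budget=0
        )
        res = annotate_matrix(_matrix({MIR: [1, 1]}), [lib])
        assert res.annotations.loc[MIR, "identifier"] == "mir-a2"

    def test_duplicate_identifiers_rejected(self):
        with pytest.raises(ValueError):
            ReferenceLibrary(rank=1, name="bad", entries=(("x", MIR), ("x", MIR)))

    def test_duplicate_ranks_rejected(self):
        libs = self.make_libs()
        clone = ReferenceLibrary(rank=1, name="other", entries=(("y", MIR),))
        with pytest.raises(ValueError):
            annotate_matrix(_matrix({MIR: [1, 0]}), [libs[0], clone])


class TestNovelCandidateFilter:
    def make_cluster(self, count=10, length=22, fluct=1, arms=None):
        seq = "A" * length
        members = (
            ClusterRead(start=100, sequence=seq, count=count),
            ClusterRead(start=100 + fluct, sequence=seq[:-1], count=2),
        )
        return ReadCluster(members=members, arms=arms)

    def test_boundary_values_pass(self):
        decision = novel_candidate_filter(self.make_cluster(count=10, length=22, fluct=1))
        assert decision.passed

    @pytest.mark.parametrize(
        "kwargs,reason",
        [
            (dict(count=9), "read_count"),
            (dict(length=19), "length"),
            (dict(length=24), "length"),
            (dict(fluct=3), "five_prime_fluctuation"),
        ],
    )
    def test_single_rule_violations(self, kwargs, reason):
        decision = novel_candidate_filter(self.make_cluster(**kwargs))
        assert not decision.passed
        assert decision.reasons == (reason,)

    def test_rat_specific_needs_perfect_overhangs(self):
        # hairpin of 60 nt; arms with perfect 2-nt 3' overhangs:
        good = ArmPair(five_start=2, five_end=24, three_start=38, three_end=60,
                       hairpin_length=60)
        assert good.overhang_3p == 2 and good.overhang_5p == 2
        ok = novel_candidate_filter(self.make_cluster(arms=good), rat_specific=True)
        assert ok.passed
        # shift the 3p arm one nt: overhang becomes 1
        bad = ArmPair(five_start=2, five_end=24, three_start=37, three_end=59,
                      hairpin_length=60)
        assert bad.overhang_3p == 1
        res = novel_candidate_filter(self.make_cluster(arms=bad), rat_specific=True)
        assert res.reasons == ("overhang",)

    def test_rat_specific_requires_both_arms(self):
        res = novel_candidate_filter(self.make_cluster(), rat_specific=True)
        assert res.reasons == ("arms_missing",)


class TestClusterReads:
    def test_window_grouping(self):
        reads = [(100, "A" * 22, 50), (101, "A" * 21, 5), (102, "A" * 20, 3), (110, "C" * 22, 7)]
        clusters = cluster_reads(reads, window=2)
        assert len(clusters) == 2
        assert clusters[0].anchor == 100
        assert clusters[0].five_prime_fluctuation == 2
        assert clusters[1].anchor == 110
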