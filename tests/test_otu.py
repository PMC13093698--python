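import random

import numpy as np
import pytest

from nanofish.io import SampleRecord
from nanofish.otu import (
    Cluster,
    ClusterParams,
    Consensus,
    build_otu_table,
    greedy_cluster,
    majority_consensus,
    pairwise_identity,
    recluster_consensuses,
)
from nanofish.simulate import CommunityProfile, ErrorModel, synth_reference_panel


def oracle_matches(a: str, b: str) -> int:
    """Independent DP: minimum-edit global alignment, then maximum matches.

    States are (edits, -matches) minimized lexicographically, so the match
    count is the best achievable on any minimum-edit alignment.
    """
    m, n = len(a), len(b)
    prev = [(j, 0) for j in range(n + 1)]
    for i in range(1, m + 1):
        cur = [(i, 0)] + [None] * n
        for j in range(1, n + 1):
            eq = a[i - 1] == b[j - 1]
            diag = (prev[j - 1][0] + (0 if eq else 1), prev[j - 1][1] - (1 if eq else 0))
            up = (prev[j][0] + 1, prev[j][1])
            left = (cur[j - 1][0] + 1, cur[j - 1][1])
            cur[j] = min(diag, up, left)
        prev = cur
    return -prev[n][1]


def _mutate(seq, rate, rng):
    out = []
    for c in seq:
        r = rng.random()
        if r < rate * 0.7:
            out.append(rng.choice([b for b in "ACGT" if b != c]))
        elif r < rate * 0.85:
            continue
        else:
            out.append(c)
            if rng.random() < rate * 0.15:
                out.append(rng.choice("ACGT"))
    return "".join(out)


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("A" * 100, "A" * 100) == 1.0

    def test_three_substitutions(self):
        rng = random.Random(1)
        a = "".join(rng.choice("ACGT") for _ in range(100))
        b = list(a)
        for pos in (20, 50, 80):  # well-separated, so no cheaper indel path
            b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
        b = "".join(b)
        assert pairwise_identity(a, b) == pytest.approx(0.97)

    def test_matches_dp_oracle_on_random_pairs(self):
        rng = random.Random(42)
        for _ in range(60):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 45)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 45)))
            expected = oracle_matches(a, b) / min(len(a), len(b))
            assert pairwise_identity(a, b) == pytest.approx(expected, abs=1e-9)

    def test_symmetry_and_empty(self):
        a, b = "ACGTACGTAC", "ACGTTCGTAC"
        assert pairwise_identity(a, b) == pairwise_identity(b, a)
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")


def oracle_greedy(seqs, threshold, min_size):
    """Naive re-implementation of the greedy pass using the DP oracle."""
    from collections import Counter

    abundance = Counter(s for _, s in seqs)
    order = sorted(seqs, key=lambda t: (-len(t[1]), -abundance[t[1]], t[0]))
    clusters = []
    for sid, seq in order:
        for cl in clusters:
            rep = cl[0]
            ident = oracle_matches(seq, rep) / min(len(seq), len(rep))
            if ident >= threshold:
                cl[1].append(sid)
                break
        else:
            clusters.append((seq, [sid]))
    return [set(m) for _, m in clusters if len(m) >= min_size]


class TestGreedyCluster:
    def test_textbook_case(self):
        a = "ACGTACGTAC" * 10
        a_prime = a[:50] + ("C" if a[50] != "C" else "G") + a[51:]  # 99% to a
        rng = random.Random(0)
        b = _mutate(a, 0.25, rng)  # far from a
        while pairwise_identity(a, b) > 0.9:
            b = _mutate(a, 0.3, rng)
        seqs = [("r1", a), ("r2", a), ("r3", a_prime), ("r4", b)]
        outcome = greedy_cluster(seqs, ClusterParams(0.97, 1))
        sizes = sorted(c.size for c in outcome.clusters)
        assert sizes == [1, 3]

    def test_empty_input(self):
        outcome = greedy_cluster([], ClusterParams())
        assert outcome.clusters == [] and outcome.unclustered_ids == []

    def test_min_cluster_size_discards(self):
        seqs = [("a", "ACGT" * 30), ("b", "TGCA" * 30)]
        outcome = greedy_cluster(seqs, ClusterParams(0.97, 2))
        assert not outcome.clusters
        assert sorted(outcome.unclustered_ids) == ["a", "b"]

    def test_agrees_with_oracle_on_simulated_reads(self):
        """200 noisy reads from 3 distant references: same memberships as
        an exhaustive reference implementation."""
        panel = synth_reference_panel(
            3, 0, target_identity_range=(0.75, 0.85), seed=33
        )
        refs = [r.sequence for r in panel if r.species != "Homo sapiens"]
        rng = random.Random(7)
        seqs = []
        for i in range(200):
            ref = refs[i % 3]
            seqs.append((f"r{i:03d}", _mutate(ref, 0.02, rng)))
        params = ClusterParams(identity_threshold=0.90, min_cluster_size=1)
        ours = greedy_cluster(seqs, params)
        expected = oracle_greedy(seqs, 0.90, 1)
        assert len(ours.clusters) == 3
        assert sorted(
            (sorted(c.member_ids) for c in ours.clusters)
        ) == sorted(sorted(m) for m in expected)

    def test_deterministic(self):
        rng = random.Random(5)
        seqs = [
            (f"r{i}", "".join(rng.choice("ACGT") for _ in range(60)))
            for i in range(40)
        ]
        a = greedy_cluster(seqs, ClusterParams(0.8, 1))
        b = greedy_cluster(list(seqs), ClusterParams(0.8, 1))
        assert [c.member_ids for c in a.clusters] == [c.member_ids for c in b.clusters]


class TestConsensus:
    def test_identical_members(self):
        seq = "ACGTACGTGG" * 12
        cluster = Cluster(seq, ["a", "b", "c"])
        cons = majority_consensus(cluster, {m: seq for m in "abc"})
        assert cons.sequence == seq
        assert cons.support == 3

    def test_single_substitution_outvoted(self):
        seq = "ACGTACGTGG" * 12
        variant = seq[:60] + ("A" if seq[60] != "A" else "T") + seq[61:]
        members = {f"m{i}": seq for i in range(4)}
        members["mut"] = variant
        cons = majority_consensus(Cluster(seq, list(members)), members)
        assert cons.sequence == seq

    def test_noisy_members_recover_truth(self):
        """9 members at 5% error majority-vote back to the exact truth."""
        panel = synth_reference_panel(2, 0, seed=12)
        truth = panel.records[0].sequence
        rng = random.Random(19)
        members = {f"m{i}": _mutate(truth, 0.05, rng) for i in range(9)}
        rep = members["m0"]
        cons = majority_consensus(Cluster(rep, list(members)), members)
        assert pairwise_identity(cons.sequence, truth) > 0.99

    def test_below_min_size_errors(self):
        with pytest.raises(ValueError):
            majority_consensus(Cluster("ACGT", ["a"]), {"a": "ACGT"}, min_cluster_size=5)


class TestRecluster:
    def test_identical_consensuses_merge_counts(self):
        seq = "ACGT" * 40
        cons = [Consensus(seq, 10, "S1"), Consensus(seq, 7, "S2")]
        (otu,) = recluster_consensuses(cons)
        assert otu.per_sample_counts == {"S1": 10, "S2": 7}

    def test_below_threshold_stay_separate(self):
        rng = random.Random(2)
        a = "".join(rng.choice("ACGT") for _ in range(150))
        b = _mutate(a, 0.08, rng)
        assert pairwise_identity(a, b) < 0.97
        otus = recluster_consensuses([Consensus(a, 5, "S1"), Consensus(b, 5, "S1")])
        assert len(otus) == 2

    def test_support_conservation(self):
        rng = random.Random(14)
        cons = []
        for i in range(12):
            seq = "".join(rng.choice("ACGT") for _ in range(140))
            cons.append(Consensus(seq, rng.randint(5, 50), f"S{i % 3}"))
        otus = recluster_consensuses(cons)
        assert sum(o.total_count for o in otus) == sum(c.support for c in cons)
        assert [o.otu_id for o in otus] == [
            f"OTU_{i + 1:04d}" for i in range(len(otus))
        ]
        totals = [o.total_count for o in otus]
        assert totals == sorted(totals, reverse=True)


class TestOtuTable:
    def _samples(self, ids):
        return [SampleRecord(s, f"BC{i + 1:02d}", "environmental") for i, s in enumerate(ids)]

    def test_structural_zero(self):
        from nanofish.otu import Otu

        otus = [
            Otu("OTU_0001", "ACGT" * 30, {"S1": 10, "S2": 5}),
            Otu("OTU_0002", "TGCA" * 30, {"S1": 3}),
        ]
        table = build_otu_table(otus, self._samples(["S1", "S2", "S3"]))
        assert table.counts.shape == (2, 3)
        assert table.counts.at["OTU_0002", "S2"] == 0
        assert list(table.counts.sum(axis=0)) == [13, 5, 0]

    def test_empty_otu_list(self):
        table = build_otu_table([], self._samples(["S1", "S2"]))
        assert table.counts.shape == (0, 2)

    def test_orphan_sample_errors(self):
        from nanofish.otu import Otu

        with pytest.raises(ValueError, match="unknown samples"):
            build_otu_table(
                [Otu("OTU_0001", "ACGT", {"GHOST": 5})], self._samples(["S1"])
            )
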