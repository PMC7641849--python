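"""Greedy clustering, profiles, UPGMA, iterative merging, and grafting."""

import numpy as np
import pytest

from domaincensus import tree_metrics
from domaincensus.cluster_graft import (
    ClusterParams,
    SeqCluster,
    SeqRecord,
    align_cluster,
    build_cluster_tree,
    graft,
    greedy_cluster,
    merge_iterate,
    pairwise_identity,
    profile_similarity,
    schematic_tree,
    select_representatives,
    self_score,
    upgma,
    _AA_INDEX,
)
from domaincensus.synthetic_data import SeqSimSpec, simulate_sequence_families


def brute_force_identity(a: str, b: str) -> float:
    """Exhaustive global alignment (match 1, mismatch 0, linear gap -1)."""
    la, lb = len(a), len(b)
    NEG = float("-inf")
    # DP over (score, matches at an optimal path) with match-count tie-break
    best = [[(NEG, 0, 0)] * (lb + 1) for _ in range(la + 1)]
    best[0][0] = (0.0, 0, 0)
    for i in range(la + 1):
        for j in range(lb + 1):
            s, m, cols = best[i][j]
            if s == NEG:
                continue
            if i < la and j < lb:
                match = 1 if a[i] == b[j] else 0
                cand = (s + match, m + match, cols + 1)
                if cand[:1] > best[i + 1][j + 1][:1] or (
                    cand[0] == best[i + 1][j + 1][0] and cand > best[i + 1][j + 1]
                ):
                    best[i + 1][j + 1] = cand
            for di, dj in ((1, 0), (0, 1)):
                if i + di <= la and j + dj <= lb:
                    cand = (s - 1, m, cols + 1)
                    tgt = best[i + di][j + dj]
                    if cand[0] > tgt[0] or (cand[0] == tgt[0] and cand > tgt):
                        best[i + di][j + dj] = cand
    s, m, cols = best[la][lb]
    return m / cols


class TestPairwiseIdentity:
    def test_identical(self):
        r = SeqRecord("a", "ACDEFGHIKL")
        assert pairwise_identity(r, SeqRecord("b", "ACDEFGHIKL")) == 1.0

    def test_disjoint_alphabets(self):
        a = SeqRecord("a", "AAAAAA")
        b = SeqRecord("b", "WWWWWW")
        assert pairwise_identity(a, b) == 0.0

    def test_single_substitution(self):
        a = SeqRecord("a", "ACDEFG")
        b = SeqRecord("b", "ACDEYG")
        assert pairwise_identity(a, b) == pytest.approx(5 / 6)
        assert brute_force_identity("ACDEFG", "ACDEYG") == pytest.approx(5 / 6)

    def test_symmetric(self):
        a = SeqRecord("a", "MKVLITAGG")
        b = SeqRecord("b", "KVLPITA")
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            SeqRecord("a", "")


class TestGreedyCluster:
    def test_identical_sequences_one_cluster(self):
        seqs = [SeqRecord(f"s{i}", "ACDEFGHIKL") for i in range(3)]
        clusters = greedy_cluster(seqs, 0.5)
        assert len(clusters) == 1 and len(clusters[0].members) == 3

    def test_two_distant_families_two_clusters(self):
        seqs = [
            SeqRecord("a1", "ACDEFGHIKL"),
            SeqRecord("a2", "ACDEFGHIKI"),
            SeqRecord("b1", "WWNQSTPWWN"),
        ]
        assert len(greedy_cluster(seqs, 0.5)) == 2

    def test_threshold_one_splits_distinct(self):
        seqs = [SeqRecord("a", "ACDEF"), SeqRecord("b", "ACDEY"),
                SeqRecord("c", "ACDEF" )]
        clusters = greedy_cluster(seqs, 1.0)
        assert len(clusters) == 2

    def test_partition_recovery_on_separated_families(self):
        """Well-separated synthetic families are recovered exactly."""
        for seed in range(1, 21):
            spec = SeqSimSpec(n_families=4, members_per_family=6, root_length=120,
                              within_rate=0.08, between_rate=1.0, seed=seed)
            seqs = simulate_sequence_families(spec)
            clusters = greedy_cluster(seqs, 0.5)
            partition = {frozenset(c.member_ids) for c in clusters}
            truth = {
                frozenset(s.id for s in seqs if s.id.startswith(f"F{f:02d}"))
                for f in range(4)
            }
            assert partition == truth


class TestAlignCluster:
    def test_single_member_point_mass(self):
        cl = align_cluster(SeqCluster([SeqRecord("a", "ACD")], SeqRecord("a", "ACD")))
        assert cl.profile.shape == (3, 21)
        assert np.allclose(cl.profile.sum(axis=1), 1.0)
        assert cl.profile[0, _AA_INDEX["A"]] == 1.0

    def test_identical_members_same_as_single(self):
        seqs = [SeqRecord(f"s{i}", "ACDEF") for i in range(3)]
        cl = align_cluster(SeqCluster(list(seqs), seqs[0]))
        single = align_cluster(SeqCluster([seqs[0]], seqs[0]))
        assert np.allclose(cl.profile, single.profile)

    def test_one_site_difference_splits_column(self):
        seqs = [SeqRecord("a", "ACDEF"), SeqRecord("b", "ACDEY")]
        cl = align_cluster(SeqCluster(list(seqs), seqs[0]))
        col = cl.profile[4]
        assert col[_AA_INDEX["F"]] == pytest.approx(0.5)
        assert col[_AA_INDEX["Y"]] == pytest.approx(0.5)

    def test_insertion_becomes_gap_column(self):
        seqs = [SeqRecord("a", "ACDEF"), SeqRecord("b", "ACDXXEF")]
        cl = align_cluster(SeqCluster(list(seqs), seqs[1]))
        assert all(len(r) == len(cl.rows[0]) for r in cl.rows)
        assert np.allclose(cl.profile.sum(axis=1), 1.0)


class TestProfileSimilarity:
    def _point_profile(self, seq: str) -> np.ndarray:
        p = np.zeros((len(seq), 21))
        for i, ch in enumerate(seq):
            p[i, _AA_INDEX[ch]] = 1.0
        return p

    def test_identical_ratio_one(self):
        p = self._point_profile("ACDEFGHIKL")
        assert profile_similarity(p, p) / self_score(p) == pytest.approx(1.0)

    def test_disjoint_residues_score_zero(self):
        assert profile_similarity(
            self._point_profile("AAAAAA"), self._point_profile("WWWWWW")
        ) == 0.0

    def test_best_offset_beats_zero_offset(self):
        """Shifted copies are recovered at the right offset."""
        p = self._point_profile("ACDEFGHIKL")
        shifted = np.vstack([p[1:], self._point_profile("A")])
        best = profile_similarity(p, shifted)
        # independent oracle: enumerate offsets explicitly
        def at_offset(off):
            a0, b0 = max(0, off), max(0, -off)
            ov = min(len(p) - a0, len(shifted) - b0)
            dot = sum(float(p[a0 + k] @ shifted[b0 + k]) for k in range(ov))
            return (dot - ov / 20.0) / ov
        oracle = max(at_offset(o) for o in range(-5, 6))
        assert best == pytest.approx(oracle)
        assert best >= at_offset(0)

    def test_symmetric(self, rng):
        pa = self._point_profile("ACDEFGHIKL")
        pb = self._point_profile("CDEFGHIK")
        assert profile_similarity(pa, pb) == pytest.approx(
            profile_similarity(pb, pa)
        )


class TestUpgma:
    def test_hand_computed_join_heights(self):
        d = np.array([[0.0, 2, 8], [2, 0, 8], [8, 8, 0]])
        tree = upgma(d, ["A", "B", "C"])
        dist = tree_metrics.root_to_tip_distances(tree)
        assert dist == pytest.approx({"A": 4.0, "B": 4.0, "C": 4.0})
        # A and B join at height 1: their terminal branches are length 1
        ab = tree_metrics.extract_subtree(tree, {"A", "B"})
        assert tree_metrics.root_to_tip_distances(ab) == pytest.approx(
            {"A": 1.0, "B": 1.0}
        )

    def test_two_items_join_at_half_distance(self):
        tree = upgma(np.array([[0.0, 3], [3, 0]]), ["X", "Y"])
        assert tree_metrics.root_to_tip_distances(tree) == pytest.approx(
            {"X": 1.5, "Y": 1.5}
        )

    def test_equal_distances_deterministic(self):
        d = np.ones((4, 4)) - np.eye(4)
        t1 = tree_metrics.write_newick(upgma(d, list("DCBA")))
        t2 = tree_metrics.write_newick(upgma(d, list("ABCD")))
        assert t1 == t2

    def test_nan_rejected(self):
        d = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="NaN"):
            upgma(d, ["A", "B"])


class TestMergeIterate:
    def _cluster(self, seqs):
        members = [SeqRecord(*s) for s in seqs]
        return align_cluster(SeqCluster(members, members[0]))

    def test_identical_profiles_merge_first_round(self):
        a = self._cluster([("a1", "ACDEFGHIKL")])
        b = self._cluster([("b1", "ACDEFGHIKL")])
        out = merge_iterate([a, b], ClusterParams(iterations=1))
        assert len(out) == 1
        assert sorted(out[0].member_ids) == ["a1", "b1"]

    def test_dissimilar_clusters_unchanged(self):
        a = self._cluster([("a1", "AAAACAAAAC" * 3)])
        b = self._cluster([("b1", "WWNQWWNQWW" * 3)])
        out = merge_iterate([a, b], ClusterParams())
        assert len(out) == 2

    def test_transitive_chain_merges(self):
        base = "ACDEFGHIKLMNPQRSTVWY" * 2
        mid = base[:20] + "IKLMNPQRSTVWYACDEFGH"
        far = "IKLMNPQRSTVWYACDEFGH" * 2
        a, b, c = (self._cluster([(x, s)]) for x, s in
                   (("a1", base), ("b1", mid), ("c1", far)))
        out = merge_iterate([a, b, c], ClusterParams(iterations=1))
        # b shares half its columns with each of a and c; a and c share none
        # at a single offset yet all three coalesce through b
        assert len(out) == 1

    def test_cluster_count_non_increasing(self):
        seqs = simulate_sequence_families(SeqSimSpec(seed=11, n_families=4,
                                                     members_per_family=4))
        clusters = [align_cluster(c) for c in greedy_cluster(seqs, 0.5)]
        out = merge_iterate(clusters, ClusterParams())
        assert len(out) <= len(clusters)


class TestClusterTree:
    def test_two_member_cherry(self):
        seqs = [SeqRecord("a", "ACDEFGHIKL"), SeqRecord("b", "ACDEFGHIKY")]
        tree = build_cluster_tree(align_cluster(SeqCluster(list(seqs), seqs[0])))
        d = tree_metrics.root_to_tip_distances(tree)
        assert d == pytest.approx({"a": 0.05, "b": 0.05})

    def test_singleton_tree(self):
        seqs = [SeqRecord("a", "ACDEF")]
        tree = build_cluster_tree(align_cluster(SeqCluster(list(seqs), seqs[0])))
        assert [l.taxon.label for l in tree.leaf_node_iter()] == ["a"]

    def test_nj_recovers_generating_topology(self):
        # two tight pairs, far apart: ((a1,a2),(b1,b2))
        seqs = [
            SeqRecord("a1", "ACDEFGHIKLACDEFGHIKL"),
            SeqRecord("a2", "ACDEFGHIKLACDEFGHIKY"),
            SeqRecord("b1", "WWNQSTPWNQWWNQSTPWNQ"),
            SeqRecord("b2", "WWNQSTPWNQWWNQSTPWNY"),
        ]
        tree = build_cluster_tree(align_cluster(SeqCluster(list(seqs), seqs[0])))
        mrca_a = tree_metrics.extract_subtree(tree, {"a1", "a2"})
        assert {l.taxon.label for l in mrca_a.leaf_node_iter()} == {"a1", "a2"}


class TestGraftAndPipeline:
    def test_graft_tip_union(self):
        seqs = simulate_sequence_families(
            SeqSimSpec(seed=2, n_families=2, members_per_family=3)
        )
        grafted = schematic_tree(seqs)
        tips = {l.taxon.label for l in grafted.composite.leaf_node_iter()}
        assert tips == {s.id for s in seqs}
        backbone_tips = {l.taxon.label for l in grafted.backbone.leaf_node_iter()}
        assert len(backbone_tips) == len(grafted.subtrees)

    def test_singleton_clusters_relabel_backbone(self):
        seqs = [SeqRecord("a", "AAAACAAAAC" * 3), SeqRecord("b", "WWNQWWNQWW" * 3)]
        grafted = schematic_tree(seqs)
        assert {l.taxon.label for l in grafted.composite.leaf_node_iter()} == {"a", "b"}

    def test_missing_subtree_rejected(self):
        seqs = [SeqRecord("a", "AAAACAAAAC" * 3), SeqRecord("b", "WWNQWWNQWW" * 3)]
        grafted = schematic_tree(seqs)
        with pytest.raises(ValueError, match="correspond"):
            graft(grafted.backbone, {"a": grafted.subtrees["a"]})

    def test_composite_newick_round_trip_and_determinism(self):
        spec = SeqSimSpec(seed=9, n_families=3, members_per_family=4)
        n1 = tree_metrics.write_newick(
            schematic_tree(simulate_sequence_families(spec)).composite
        )
        n2 = tree_metrics.write_newick(
            schematic_tree(simulate_sequence_families(spec)).composite
        )
        assert n1 == n2
        back = tree_metrics.parse_newick(n1, missing_length="zero")
        assert {l.taxon.label for l in back.leaf_node_iter()} == {
            s.id for s in simulate_sequence_families(spec)
        }

    def test_representative_census_threshold(self):
        seqs = [
            SeqRecord("a1", "ACDEFGHIKL" * 3),
            SeqRecord("a2", "ACDEFGHIKL" * 3),
            SeqRecord("b1", "WWNQSTPWNQ" * 3),
        ]
        reps = select_representatives(seqs, 0.85)
        assert {r.id for r in reps} == {"a1", "b1"}
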