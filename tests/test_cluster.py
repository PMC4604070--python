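import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from oracles import adjusted_rand_index
from toxdup.cluster import (
    DuplicationGroup,
    _select_merge,
    build_group_tree,
    cluster_sequences,
    duplication_report,
    evalue_to_distance,
    merge_alignments,
    upgma,
)
from toxdup.compare import align_hmms
from toxdup.formats import Alignment, SequenceRecord, TreeNode, write_newick
from toxdup.hmm import build_profile_hmm
from toxdup.simulate import FamilySimSpec, simulate_family_set

AA = "ACDEFGHIKLMNPQRSTVWY"


def _partition_labels(result, ids):
    membership = result.membership()
    return [membership[i] for i in ids]


class TestSelectMerge:
    def test_strict_cutoff(self):
        pair = frozenset(("a", "b"))
        assert _select_merge({pair: 1.0e-19}, 1.0e-20) is None
        chosen = _select_merge({pair: 1.0e-21}, 1.0e-20)
        assert chosen == (pair, 1.0e-21)

    def test_boundary_value_not_merged(self):
        pair = frozenset(("a", "b"))
        assert _select_merge({pair: 1.0e-20}, 1.0e-20) is None

    def test_lowest_e_wins_with_lexicographic_ties(self):
        e = {
            frozenset(("b", "c")): 1e-30,
            frozenset(("a", "d")): 1e-30,
            frozenset(("a", "z")): 1e-25,
        }
        chosen = _select_merge(e, 1e-20)
        assert chosen == (frozenset(("a", "d")), 1e-30)


class TestClusterSequences:
    def test_two_identical_sequences_one_group(self, rng):
        residues = "".join(AA[i] for i in rng.integers(0, 20, 100))
        seqs = [
            SequenceRecord(id="x1", residues=residues),
            SequenceRecord(id="x2", residues=residues),
        ]
        result = cluster_sequences(seqs, seed=1)
        assert len(result.groups) == 1
        assert result.groups[0].member_ids == ("x1", "x2")
        assert not result.singlets
        assert result.merge_log[0][2] < 1e-20

    def test_empty_input(self):
        with pytest.raises(ValueError, match="no sequences"):
            cluster_sequences([])

    def test_single_sequence(self):
        result = cluster_sequences([SequenceRecord(id="only", residues="ACDEFGHIKL")])
        assert not result.groups
        assert len(result.singlets) == 1
        assert result.singlets[0].member_ids == ("only",)
        assert write_newick(result.tree) == "g1;"

    def test_planted_families_recovered(self):
        spec = FamilySimSpec(
            n_families=3, members_per_family=4, ancestor_length=50,
            substitution_prob=0.10, n_decoys=6, seed=5,
        )
        seqs, truth = simulate_family_set(spec)
        result = cluster_sequences(seqs, seed=5)
        assert len(result.groups) == 3
        assert len(result.singlets) == 6
        ids = sorted(truth.labels)
        planted = [truth.labels[i] if truth.labels[i] != "decoy" else i for i in ids]
        assert adjusted_rand_index(planted, _partition_labels(result, ids)) == 1.0
        assert all(e < result.cutoff for _, _, e in result.merge_log)

    def test_input_order_permutation_invariance(self):
        spec = FamilySimSpec(n_families=2, members_per_family=3, ancestor_length=50,
                             substitution_prob=0.08, n_decoys=4, seed=3)
        seqs, _ = simulate_family_set(spec)
        r1 = cluster_sequences(seqs, seed=3)
        rng = np.random.default_rng(0)
        shuffled = [seqs[i] for i in rng.permutation(len(seqs))]
        r2 = cluster_sequences(shuffled, seed=3)
        assert r1.membership() == r2.membership()
        assert write_newick(r1.tree) == write_newick(r2.tree)

    def test_every_sequence_in_exactly_one_group(self):
        spec = FamilySimSpec(n_families=2, members_per_family=3, ancestor_length=40,
                             substitution_prob=0.05, n_decoys=3, seed=9)
        seqs, _ = simulate_family_set(spec)
        result = cluster_sequences(seqs, seed=9)
        seen = [m for g in result.all_groups() for m in g.member_ids]
        assert sorted(seen) == sorted(s.id for s in seqs)
        # group count bounded, merge count <= n-1
        assert len(result.merge_log) <= len(seqs) - 1

    def test_single_pass_mode(self):
        spec = FamilySimSpec(n_families=2, members_per_family=3, ancestor_length=50,
                             substitution_prob=0.05, n_decoys=3, seed=13)
        seqs, truth = simulate_family_set(spec)
        result = cluster_sequences(seqs, seed=13, single_pass=True)
        ids = sorted(truth.labels)
        planted = [truth.labels[i] if truth.labels[i] != "decoy" else i for i in ids]
        assert adjusted_rand_index(planted, _partition_labels(result, ids)) == 1.0


class TestMergeAlignments:
    def test_weave_identical(self, rng):
        residues = "".join(AA[i] for i in rng.integers(0, 20, 30))
        a = Alignment.from_records([SequenceRecord(id="a", residues=residues)])
        b = Alignment.from_records([SequenceRecord(id="b", residues=residues)])
        ha = build_profile_hmm(a, name="a")
        hb = build_profile_hmm(b, name="b")
        merged = merge_alignments(a, b, ha, hb, align_hmms(ha, hb))
        assert merged.n_rows == 2
        assert merged.ids() == ["a", "b"]
        assert [r.residues.replace("-", "") for r in merged.members] == [residues] * 2

    def test_weave_preserves_residues(self, rng):
        r1 = "".join(AA[i] for i in rng.integers(0, 20, 25))
        r2 = r1[:10] + r1[15:]  # deletion variant
        a = Alignment.from_records([SequenceRecord(id="a", residues=r1)])
        b = Alignment.from_records([SequenceRecord(id="b", residues=r2)])
        ha, hb = build_profile_hmm(a, name="a"), build_profile_hmm(b, name="b")
        pair = align_hmms(ha, hb)
        merged = merge_alignments(a, b, ha, hb, pair)
        assert merged.members[0].residues.replace("-", "") == r1
        assert merged.members[1].residues.replace("-", "") == r2

    def test_empty_alignment_rejected(self, rng):
        a = Alignment.from_records([SequenceRecord(id="a", residues="AAAA")])
        b = Alignment.from_records([SequenceRecord(id="b", residues="CCCC")])
        ha = build_profile_hmm(a, name="a", pseudocount_weight=1e-9)
        hb = build_profile_hmm(b, name="b", pseudocount_weight=1e-9)
        with pytest.raises(ValueError, match="empty"):
            merge_alignments(a, b, ha, hb, align_hmms(ha, hb))


class TestUpgma:
    def test_single_leaf_tree(self):
        g = DuplicationGroup("g1", ("s1",),
                             Alignment.from_records([SequenceRecord(id="s1", residues="ACD")]),
                             None)
        from toxdup.cluster import GroupingResult
        result = GroupingResult(groups=[], singlets=[g], tree=TreeNode(), cutoff=1e-20,
                                merge_log=[])
        assert write_newick(build_group_tree(result, {})) == "g1;"

    def test_first_cherry_is_closest_pair(self):
        d = {
            frozenset(("g1", "g2")): 1.0,
            frozenset(("g1", "g3")): 4.0,
            frozenset(("g2", "g3")): 4.0,
        }
        tree = upgma(["g1", "g2", "g3"], d)
        assert write_newick(tree) == "((g1:0.5,g2:0.5):1.5,g3:2);"

    def test_against_scipy_average_linkage(self, rng):
        for _ in range(10):
            n = 8
            labels = [f"g{i}" for i in range(n)]
            m = rng.uniform(1, 10, size=(n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            d = {
                frozenset((labels[i], labels[j])): m[i, j]
                for i in range(n)
                for j in range(i + 1, n)
            }
            mine = upgma(labels, d)
            Z = hierarchy.linkage(squareform(m), method="average")
            # compare clade sets
            def clades(node, acc):
                leaves = sorted(node.leaf_labels())
                if len(leaves) > 1:
                    acc.add(tuple(leaves))
                for c in node.children:
                    clades(c, acc)
                return acc

            mine_clades = clades(mine, set())
            scipy_clades = set()
            members = {i: [labels[i]] for i in range(n)}
            for k, (x, y, _, _) in enumerate(Z):
                merged = sorted(members[int(x)] + members[int(y)])
                members[n + k] = merged
                scipy_clades.add(tuple(merged))
            assert mine_clades == scipy_clades

    def test_evalue_distance_transform(self):
        assert evalue_to_distance(1e-300) == pytest.approx(0.0)
        assert evalue_to_distance(0.0) == pytest.approx(0.0)
        assert evalue_to_distance(1.0) == pytest.approx(300.0)
        assert evalue_to_distance(1e-30) == pytest.approx(270.0)


class TestDuplicationReport:
    @staticmethod
    def _fake_result(group_sizes, n_singlets):
        from toxdup.cluster import GroupingResult

        groups, singlets = [], []
        counter = 0
        for gi, size in enumerate(group_sizes, start=1):
            members = tuple(f"m{counter + k}" for k in range(size))
            counter += size
            aln = Alignment.from_records(
                [SequenceRecord(id=m, residues="ACD") for m in members]
            )
            groups.append(DuplicationGroup(f"g{gi}", members, aln, None))
        for si in range(n_singlets):
            mid = f"m{counter}"
            counter += 1
            aln = Alignment.from_records([SequenceRecord(id=mid, residues="ACD")])
            singlets.append(
                DuplicationGroup(f"g{len(group_sizes) + si + 1}", (mid,), aln, None)
            )
        return GroupingResult(groups=groups, singlets=singlets, tree=TreeNode(),
                              cutoff=1e-20, merge_log=[])

    def test_paper_scale_partition(self):
        # 13 groups totalling 36 members + 19 singlets
        sizes = [2] * 8 + [4] * 5  # 16 + 20 = 36
        result = self._fake_result(sizes, 19)
        report = duplication_report(result)
        assert report["n_total"] == 55
        assert report["n_groups"] == 13
        assert report["n_in_groups"] == 36
        assert report["n_singlets"] == 19
        assert report["fraction_pct"] == 65

    def test_all_singlets(self):
        report = duplication_report(self._fake_result([], 7))
        assert report["fraction_pct"] == 0

    def test_detected_overlap_percentages(self):
        sizes = [2] * 8 + [4] * 5
        result = self._fake_result(sizes, 19)
        group_members = [m for g in result.groups for m in g.member_ids]
        singlet_members = [g.member_ids[0] for g in result.singlets]
        detected = set(group_members[:6]) | set(singlet_members[:6])  # 6 + 6 = 12
        report = duplication_report(result, detected_ids=detected)
        assert report["n_detected"] == 12
        assert report["detected_pct"] == 22
        assert report["detected_in_groups"] == 6
        assert report["detected_in_groups_pct"] == 50
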