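import itertools
import math

import numpy as np
import pytest
from scipy import stats

from bhtreesim import (
    DuplicateLabelError,
    NewickParseError,
    Node,
    PhyloTree,
    RandomStream,
    SamplingError,
    ShiftConfig,
    SimConfig,
    assemble_tree,
    prune_extinct,
    read_newick,
    sample_tips,
    shift_report,
    simulate_age,
    simulate_taxa,
    tree_stats,
    write_newick,
)


def _three_tip_tree(pendants):
    """((t1,t2),t3) with the given pendant lengths; all tips extant."""
    p1, p2, p3 = pendants
    nodes = {}

    def mk(i, parent, length, time, tip=False, label=None):
        nodes[i] = Node(id=i, parent=parent, length=length, time=time,
                        label=label, is_tip=tip, extant=tip)
        if parent is not None:
            nodes[parent].children.append(i)

    mk(0, None, 0.0, 1.0)
    mk(1, 0, 1.0, 2.0)
    mk(2, 1, p1, 2.0 + p1, tip=True, label="t1")
    mk(3, 1, p2, 2.0 + p2, tip=True, label="t2")
    mk(4, 0, p3, 1.0 + p3, tip=True, label="t3")
    return PhyloTree(nodes, 0, 1.0)


def _balanced_tree(pendant=1.0):
    """((t1,t2),(t3,t4)) ultrametric, all pendants equal."""
    nodes = {}

    def mk(i, parent, length, time, tip=False, label=None):
        nodes[i] = Node(id=i, parent=parent, length=length, time=time,
                        label=label, is_tip=tip, extant=tip)
        if parent is not None:
            nodes[parent].children.append(i)

    mk(0, None, 0.0, 1.0)
    mk(1, 0, 1.0, 2.0)
    mk(2, 0, 1.0, 2.0)
    mk(3, 1, pendant, 2.0 + pendant, tip=True, label="t1")
    mk(4, 1, pendant, 2.0 + pendant, tip=True, label="t2")
    mk(5, 2, pendant, 2.0 + pendant, tip=True, label="t3")
    mk(6, 2, pendant, 2.0 + pendant, tip=True, label="t4")
    return PhyloTree(nodes, 0, 1.0)


class TestAssemble:
    def test_symmetric_delta_tree(self, delta_symmetric_config):
        res = simulate_age(delta_symmetric_config, 5, RandomStream(0))
        tree = res.tree
        tree.validate()
        assert tree.n_extant_tips == 4
        assert tree.n_tips == 4
        internal = [n for n in tree.nodes.values() if not n.is_tip]
        assert len(internal) == 3
        assert tree.stem_length == pytest.approx(2.0)
        assert sorted(n.time for n in internal) == pytest.approx([2.0, 4.0, 4.0])

    def test_asymmetric_delta_tree(self, delta_asymmetric_config):
        res = simulate_age(delta_asymmetric_config, 5, RandomStream(0))
        tree = res.tree
        tree.validate()
        assert tree.n_extant_tips == 1
        assert tree.n_tips == 3
        internal = sorted(n.time for n in tree.nodes.values() if not n.is_tip)
        assert internal == pytest.approx([2.0, 4.0])

    def test_single_lineage(self):
        cfg = SimConfig(waitsp="const(10)")
        res = simulate_age(cfg, 3, RandomStream(0))
        tree = res.tree
        assert tree.n_tips == 1
        assert tree.stem_length == pytest.approx(3.0)
        assert tree.nodes[tree.root].length == 0.0


class TestPrune:
    def test_budding_delta_tree_single_survivor(self, delta_asymmetric_config):
        res = simulate_age(delta_asymmetric_config, 5, RandomStream(0))
        pruned = prune_extinct(res.tree)
        assert pruned.status == "single_survivor"
        assert pruned.tree is None

    def test_pure_birth_prune_is_identity(self):
        cfg = SimConfig(waitsp="rexp(0.7)")
        res = simulate_taxa(cfg, 8, stream=RandomStream(4))
        pruned = prune_extinct(res.tree)
        assert pruned.status == "completed"
        assert set(pruned.tree.nodes) == set(res.tree.nodes)

    def test_doubling_delta_tree_unchanged(self, delta_symmetric_config):
        res = simulate_age(delta_symmetric_config, 5, RandomStream(0))
        pruned = prune_extinct(res.tree)
        assert pruned.tree.n_tips == 4
        assert pruned.tree.is_ultrametric()

    def test_crbd_prune_properties(self):
        cfg = SimConfig(waitsp="rexp(0.9)", waitext="rexp(0.4)")
        done = 0
        for k in range(40):
            res = simulate_age(cfg, 4, RandomStream.for_replicate(300, k))
            if res.tree is None or res.tree.n_extant_tips < 2:
                continue
            pruned = prune_extinct(res.tree)
            assert pruned.tree.n_extant_tips == res.tree.n_extant_tips
            full = tree_stats(res.tree)
            rec = tree_stats(pruned.tree)
            assert rec.total_branch_length <= full.total_branch_length + 1e-12
            assert pruned.tree.is_ultrametric()
            # binary after suppression
            for node in pruned.tree.nodes.values():
                if not node.is_tip:
                    assert len(node.children) == 2
            pruned.tree.validate()
            done += 1
        assert done > 5

    def test_all_extinct_status(self):
        cfg = SimConfig(waitsp="const(3)", waitext="const(1)")
        from bhtreesim import cut_at_time

        res = simulate_age(cfg, 2, RandomStream(0))
        tree = assemble_tree(res.lineages, horizon=2.0)
        assert prune_extinct(tree).status == "extinct"


class TestSampleTips:
    def test_frac_one_identity(self, stream):
        tree = _balanced_tree()
        out = sample_tips(tree, 1.0, "uniform", stream)
        assert set(out.nodes) == set(tree.nodes)

    def test_uniform_all_subsets_equifrequent(self):
        """Exhaustive oracle: all C(4,2)=6 pairs equally likely."""
        tree = _balanced_tree()
        s = RandomStream(31)
        counts = {}
        n = 6000
        for _ in range(n):
            out = sample_tips(tree, 0.5, "uniform", s)
            key = tuple(sorted(t.label for t in out.tip_nodes()))
            counts[key] = counts.get(key, 0) + 1
        pairs = list(itertools.combinations(["t1", "t2", "t3", "t4"], 2))
        assert set(counts) == set(pairs)
        obs = [counts[p] for p in pairs]
        assert stats.chisquare(obs).pvalue > 0.01

    @staticmethod
    def _pair_probs_without_replacement(weights, k):
        """Brute-force oracle: exact subset probabilities of successive
        weighted draws without replacement."""
        n = len(weights)
        probs = {}
        for perm in itertools.permutations(range(n), k):
            p, left = 1.0, list(range(n))
            for i in perm:
                total = sum(weights[j] for j in left)
                p *= weights[i] / total
                left.remove(i)
            key = tuple(sorted(perm))
            probs[key] = probs.get(key, 0.0) + p
        return probs

    def test_proportional_matches_bruteforce(self):
        pendants = [2.0, 1.0, 1.0]
        tree = _three_tip_tree(pendants)
        tree.validate()
        oracle = self._pair_probs_without_replacement(pendants, 2)
        s = RandomStream(32)
        n = 10_000
        counts = {k: 0 for k in oracle}
        for _ in range(n):
            out = sample_tips(tree, 2 / 3, "proportional", s)
            labels = sorted(t.label for t in out.tip_nodes())
            key = tuple(int(l[1:]) - 1 for l in labels)
            counts[key] += 1
        obs = np.array([counts[k] for k in sorted(oracle)])
        exp = np.array([oracle[k] * n for k in sorted(oracle)])
        assert stats.chisquare(obs, exp).pvalue > 0.01

    def test_proportional_zero_pendants_error(self, stream):
        cfg = SimConfig(waitsp="const(2)")
        res = simulate_taxa(cfg, 4, stream=RandomStream(0))
        # first-passage cut puts zero pendants on every tip here
        with pytest.raises(SamplingError):
            sample_tips(res.tree, 0.5, "proportional", stream)

    def test_too_few_after_rounding(self, stream):
        tree = _balanced_tree()
        with pytest.raises(SamplingError):
            sample_tips(tree, 0.25, "uniform", stream)

    def test_requires_extant_only(self, stream, delta_asymmetric_config):
        res = simulate_age(delta_asymmetric_config, 5, RandomStream(0))
        with pytest.raises(SamplingError):
            sample_tips(res.tree, 0.5, "uniform", stream)


class TestTreeStats:
    def test_doubling_tree(self, delta_symmetric_config):
        res = simulate_age(delta_symmetric_config, 5, RandomStream(0))
        st_ = tree_stats(res.tree)
        assert st_.extant_tips == 4
        assert st_.oldest_branching_time == pytest.approx(2.0)
        assert st_.stem_age == pytest.approx(5.0)
        assert st_.ltt == [(0.0, 1), (2.0, 2), (4.0, 4)]
        # 1 + 2*1 + ... total branch length: stem 2 + 2 edges of 2 + 4 of 1
        assert st_.total_branch_length == pytest.approx(2 + 4 + 4)

    def test_budding_tree(self, delta_asymmetric_config):
        res = simulate_age(delta_asymmetric_config, 5, RandomStream(0))
        st_ = tree_stats(res.tree)
        assert st_.total_tips == 3 and st_.extant_tips == 1

    def test_one_tip_tree(self):
        res = simulate_age(SimConfig(waitsp="const(10)"), 3, RandomStream(0))
        st_ = tree_stats(res.tree)
        assert st_.extant_tips == 1
        assert st_.oldest_branching_time is None


def _trees_close(a, b, tol=1e-9):
    """Label/topology/length comparison via canonical nested tuples."""

    def canon(tree, nid):
        node = tree.nodes[nid]
        if node.is_tip and not node.children:
            return (node.label, round(node.length, 9))
        subs = sorted((canon(tree, c) for c in node.children), key=repr)
        return (tuple(subs), round(node.length, 9))

    return (
        canon(a, a.root) == canon(b, b.root)
        and math.isclose(a.stem_length, b.stem_length, rel_tol=tol, abs_tol=1e-9)
    )


class TestNewick:
    def test_one_tip_tree_stem(self):
        res = simulate_age(SimConfig(waitsp="const(10)"), 3, RandomStream(0))
        text = write_newick(res.tree)
        assert text.endswith(":3;")
        back = read_newick(text)
        assert back.stem_length == pytest.approx(3.0)
        assert back.n_tips == 1

    def test_doubling_round_trip(self, delta_symmetric_config):
        res = simulate_age(delta_symmetric_config, 5, RandomStream(0))
        back = read_newick(write_newick(res.tree))
        assert _trees_close(res.tree, back)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_random_tree_round_trip(self, seed):
        cfg = SimConfig(waitsp="rexp(0.9)", waitext="rexp(0.2)", mode="asymmetric")
        res = simulate_age(cfg, 5, RandomStream(seed))
        if res.tree is None:
            pytest.skip("extinct realization")
        back = read_newick(write_newick(res.tree))
        assert _trees_close(res.tree, back)
        back.validate()

    def test_malformed_raises(self):
        with pytest.raises(NewickParseError):
            read_newick("((A,B;")

    def test_duplicate_labels_flagged(self):
        with pytest.raises(DuplicateLabelError):
            read_newick("(A:1,A:2):0;")

    def test_extinct_marking_convention(self, delta_asymmetric_config):
        res = simulate_age(delta_asymmetric_config, 5, RandomStream(0))
        back = read_newick(write_newick(res.tree))
        assert back.n_extant_tips == 1
        assert back.n_tips == 3

    def test_nhx_annotations_embedded(self):
        cfg = SimConfig(waitsp="rexp(1)",
                        shiftsp=ShiftConfig(prob=1.0, strength="const(0.5)"))
        res = simulate_age(cfg, 3, RandomStream(5))
        text = write_newick(res.tree, annotations=True)
        assert "&&NHX" in text and "sp_factor=" in text


class TestShiftReport:
    def test_no_shifts(self):
        cfg = SimConfig(waitsp="rexp(1)")
        res = simulate_age(cfg, 4, RandomStream(6))
        rep = shift_report(res.tree)
        assert (rep.table.sp_factor == 1.0).all()
        assert (rep.table.sp_shifted == 0).all()
        assert set(rep.vectors()) == {
            "shifted.sp.living", "shifted.sp.extinct",
            "shifted.ext.living", "shifted.ext.extinct",
        }

    def test_certain_delta_shift(self):
        cfg = SimConfig(waitsp="rexp(1)",
                        shiftsp=ShiftConfig(prob=1.0, strength="const(0.5)"))
        res = simulate_age(cfg, 4, RandomStream(6))
        rep = shift_report(res.tree)
        non_root = rep.table[rep.table.node_id != res.tree.root]
        assert (non_root.sp_factor == 0.5).all()
        assert (non_root.sp_shifted == 1).all()
        assert (rep.shifted_sp_living == 1).all()
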