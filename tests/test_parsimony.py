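"""Event placement, polarisation and ancestral-structure reconstruction."""

import numpy as np
import pytest
from conftest import exhaustive_parsimony_cost

from exevol.events import StructuralEvent
from exevol.parsimony import (PhyloTree, map_event,
                              rank_structural_divergence,
                              reconstruct_ancestral_structure)
from exevol.pipeline import analyze_family
from exevol.simulate import SimConfig, emit_fixture, simulate_family


def _event(state, alt, mechanism="indeterminate_indel", length=3,
           span=(10, 13), exon=1):
    return StructuralEvent(event_id="e", mechanism=mechanism,
                           exon_index=exon, length_bp=length,
                           column_span=span, state_rows=frozenset(state),
                           alt_rows=frozenset(alt), evidence="internal_gap")


class TestMapEvent:
    def test_clade_carriers_map_to_stem(self):
        tree = PhyloTree.from_newick(
            "(outgroup,(Capsella,(Brassica,Arabidopsis)ba)stem)root;",
            outgroup="outgroup")
        ev = _event({"Capsella", "Brassica", "Arabidopsis"}, {"outgroup"})
        pl = map_event(tree, ev)
        assert pl.branches == ["stem"]
        assert pl.cost == 1

    def test_single_leaf_carrier_terminal_branch(self):
        tree = PhyloTree.from_newick("(o,(a,(b,c)n1)n2)root;", outgroup="o")
        ev = _event({"b"}, {"o", "a", "c"})
        pl = map_event(tree, ev)
        assert pl.branches == ["b"]

    def test_disjoint_carriers_two_origins(self):
        tree = PhyloTree.from_newick(
            "(o,((a,b)n1,(c,d)n2)n3)root;", outgroup="o")
        ev = _event({"a", "d"}, {"o", "b", "c"})
        pl = map_event(tree, ev)
        assert sorted(pl.branches) == ["a", "d"]
        assert pl.cost == 2

    def test_missing_carriers_raise(self):
        tree = PhyloTree.from_newick("(a,b)root;")
        with pytest.raises(ValueError, match="ghost"):
            map_event(tree, _event({"ghost"}, {"a", "b"}))

    def test_outgroup_polarises_indeterminate_indel(self):
        tree = PhyloTree.from_newick("(o,(a,(b,c)n1)n2)root;", outgroup="o")
        # gap present in outgroup and a: root gapped, carriers = b,c
        ev = _event({"o", "a"}, {"b", "c"})
        pl = map_event(tree, ev)
        assert pl.mechanism == "intraexonic_insertion"
        assert pl.carrier_genes == frozenset({"b", "c"})

    @pytest.mark.parametrize("trial", range(40))
    def test_cost_matches_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(6, 9))
        from exevol.simulate import random_tree
        tree = random_tree(n, rng)
        leaves = tree.leaf_ids()
        k = int(rng.integers(1, len(leaves)))
        carriers = set(rng.choice(leaves, size=k, replace=False))
        ev = _event(carriers, set(leaves) - carriers)
        pl = map_event(tree, ev, outgroup=None)
        oracle = exhaustive_parsimony_cost(
            tree, {lf: int(lf in carriers) for lf in leaves})
        assert pl.cost == oracle

    def test_duplicate_leaf_does_not_change_placement(self):
        t1 = PhyloTree.from_newick("(o,(a,(b,c)n1)n2)root;", outgroup="o")
        t2 = PhyloTree.from_newick("(o,(a,((b,b2)bb,c)n1)n2)root;",
                                   outgroup="o")
        ev1 = _event({"b", "c"}, {"o", "a"})
        ev2 = _event({"b", "b2", "c"}, {"o", "a"})
        pl1 = map_event(t1, ev1)
        pl2 = map_event(t2, ev2)
        assert pl1.branches == pl2.branches == ["n1"]
        assert pl1.mechanism == pl2.mechanism


class TestReconstruction:
    def test_no_events_every_node_equal(self):
        fs, tree, hist = simulate_family(SimConfig(
            seed=5, event_rates={k: 0.0 for k in
                                 ("intraexonic_insertion",)},
            subs_per_branch=0.0))
        aln, events, placements, structures, *_ = analyze_family(fs, tree)
        assert events == []
        lens = {tuple(st.exon_lengths) for st in structures.values()}
        assert len(lens) == 1

    def test_terminal_insertion_leaves_root_at_majority(self):
        """One 3-bp insertion on a terminal branch: the root keeps the
        unaffected leaves' length (Sankoff-equivalent result)."""
        fs, tree, hist = emit_fixture("flc_exon3")
        aln, events, placements, structures, *_ = analyze_family(fs, tree)
        root = structures[tree.root]
        assert root.exon_lengths[2] == 62
        # AP1's private 3-bp insertion does not leak into its ancestors
        assert structures["af"].exon_lengths[2] == 62

    def test_flc_mrca_exon3_is_68(self):
        fs, tree, hist = emit_fixture("flc_exon3")
        aln, events, placements, structures, *_ = analyze_family(fs, tree)
        assert structures["FLC_MRCA"].exon_lengths[2] == 68

    @pytest.mark.parametrize("seed", range(6))
    def test_path_conservation_on_simulated_families(self, seed):
        """Leaf exon lengths equal root lengths plus the signed placed
        event lengths along the path — equivalently, the reconstructed
        leaf structure reproduces each gene's annotation exactly."""
        fs, tree, hist = simulate_family(SimConfig(seed=seed))
        aln, events, placements, structures, *_ = analyze_family(fs, tree)
        for g in tree.leaf_ids():
            assert structures[g].exon_lengths == fs.models[g].exon_lengths


class TestDivergenceRanking:
    def _setup(self):
        tree = PhyloTree.from_newick("(o,(a,(b,c)n1)n2)root;", outgroup="o")
        ev_frame = _event({"a"}, {"o", "b", "c"}, length=3)
        ev_shift = _event({"b"}, {"o", "a", "c"}, length=4)
        pls = [map_event(tree, ev_frame), map_event(tree, ev_shift)]
        return tree, pls

    def test_frame_violations_weigh_triple(self):
        from exevol.models import FamilySet
        tree, pls = self._setup()
        ranked, subsets = rank_structural_divergence(
            FamilySet(), pls, tree, thresholds=[0.0, 10.0])
        scores = dict(ranked)
        assert scores["o"] == 0.0 and scores["c"] == 0.0
        assert scores["a"] == 1.0
        assert scores["b"] == 3.0  # 1 + non-triplet penalty 2
        assert subsets[0.0] == ["c", "o"]
        assert set(subsets[10.0]) == {"a", "b", "c", "o"}
        # nested: the permissive subset contains the strict one
        assert set(subsets[0.0]) <= set(subsets[10.0])
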