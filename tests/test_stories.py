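"""Story constraints, enumeration, set maximality, and process conflicts."""

import itertools

import networkx as nx
import pytest

import sbgndyn as sd
from sbgndyn.map_model import read_plain
from sbgndyn.stories import (Story, StorySet, check_story, conflict_relation,
                             enumerate_stories, epn_maximal_sets, final_sets,
                             maximal_valid_sets)


# ---------------------------------------------------------------------------
# Independent brute-force oracle: direct evaluation of the constraints on a
# candidate EPN set, written against the definitions, not the implementation.
# ---------------------------------------------------------------------------

def brute_is_story(pdmap, epns, min_size=2):
    epns = frozenset(epns)
    if len(epns) < min_size:
        return False
    if any(pdmap.epns[e].is_source_sink for e in epns):
        return False
    # (i) pairwise flux-path connectivity within the story
    g = nx.Graph()
    g.add_nodes_from(epns)
    for pid in pdmap.processes:
        touched = sorted((pdmap.in_(pid) | pdmap.out(pid)) & epns)
        for a, b in itertools.combinations(touched, 2):
            g.add_edge(a, b)
    if len(epns) > 1 and not nx.is_connected(g):
        return False
    for pid in pdmap.processes:
        inp, outp = pdmap.in_(pid), pdmap.out(pid)
        if outp & epns and inp and not inp & epns:     # (ii)
            return False
        if len(inp & epns) > 1 or len(outp & epns) > 1:  # (iii)/(iv)
            return False
    return True


class TestCheckStory:
    def test_transform_assoc_verdicts(self):
        """A→B with A+B→C admits {A,C}; {B,C} breaks (ii), {A,B} breaks (iii)."""
        m = sd.fixture("toy_transform_assoc")
        assert check_story(m, {"A", "C"}).ok
        v = check_story(m, {"B", "C"})
        assert not v.ok and "ii" in v.violations
        v = check_story(m, {"A", "B"})
        assert not v.ok and "iii" in v.violations

    def test_source_sink_and_size_violations(self):
        m = read_plain("epn a macromolecule\nepn ss source-sink\n"
                       "process p process\nconsume p a\nproduce p SINK\n")
        v = check_story(m, {"a", "ss"})
        assert "contains-source-or-sink" in v.violations
        assert "too-small" in check_story(m, {"a"}).violations

    def test_unknown_epn(self, worked_example):
        with pytest.raises(KeyError):
            check_story(worked_example, {"ghost"})

    def test_label_constraint(self, worked_example):
        # a and aP share label "a"; c is a complex with component label "a"
        assert check_story(worked_example, {"a", "aP", "c"},
                           label_constraint=True).ok
        v = check_story(worked_example, {"adp", "atp"}, label_constraint=True)
        assert "v" in v.violations

    def test_reactant_plus_sole_stimulator_noted_not_enforced(self):
        m = read_plain("epn a macromolecule\nepn b macromolecule\n"
                       "epn s macromolecule\nprocess p process\nconsume p a\n"
                       "produce p b\nmodulate stimulation s p\n"
                       "process r process\nconsume r s\nproduce r a\n")
        v = check_story(m, {"a", "s"})
        assert v.ok and v.notes   # warned about blocking p, still a story


class TestEnumerateStories:
    def test_transform_assoc_unique_story(self):
        m = sd.fixture("toy_transform_assoc")
        assert [sorted(s.epns) for s in enumerate_stories(m)] == [["A", "C"]]

    def test_chain_assoc_inventory(self):
        m = sd.fixture("toy_chain_assoc")
        got = {s.epns for s in enumerate_stories(m)}
        assert got == {frozenset("AB"), frozenset("CD"), frozenset("ABD")}

    def test_empty_map(self):
        assert enumerate_stories(sd.PDMap()) == []

    def test_invalid_seed_rejected(self):
        m = sd.fixture("toy_chain_assoc")
        with pytest.raises(ValueError, match="iii"):
            enumerate_stories(m, seeds=[{"B", "C"}])

    @pytest.mark.parametrize("seed", range(25))
    def test_agrees_with_brute_force(self, seed):
        """Enumeration equals exhaustive subset evaluation on small maps."""
        m = sd.random_map(sd.MapRecipe(n_epns=6, n_processes=4, seed=seed))
        pool = m.pool_epns()
        expected = {frozenset(c)
                    for r in range(2, len(pool) + 1)
                    for c in itertools.combinations(pool, r)
                    if brute_is_story(m, c)}
        assert {s.epns for s in enumerate_stories(m)} == expected

    def test_worked_example_agrees_with_brute_force(self, worked_example):
        pool = worked_example.pool_epns()
        expected = {frozenset(c)
                    for r in range(2, len(pool) + 1)
                    for c in itertools.combinations(pool, r)
                    if brute_is_story(worked_example, c)}
        got = {s.epns for s in enumerate_stories(worked_example)}
        assert got == expected
        assert frozenset({"a", "aP", "c"}) in got
        assert frozenset({"adp", "atp"}) in got


class TestStorySets:
    def test_chain_assoc_maximal_sets(self):
        m = sd.fixture("toy_chain_assoc")
        sets = maximal_valid_sets(enumerate_stories(m))
        as_sets = [{s.epns for s in ss} for ss in sets]
        assert len(sets) == 2
        assert {frozenset("AB"), frozenset("CD")} in as_sets
        assert {frozenset("ABD")} in as_sets

    def test_single_story(self):
        s = Story({"A", "C"})
        sets = maximal_valid_sets([s])
        assert len(sets) == 1 and list(sets[0]) == [s]

    def test_both_chain_sets_are_final(self):
        m = sd.fixture("toy_chain_assoc")
        sets = maximal_valid_sets(enumerate_stories(m))
        assert final_sets(sets) == sets

    def test_dominated_set_excluded(self):
        big = Story({"A", "B", "C"})
        small = Story({"A", "B"})
        other = Story({"X", "Y"})
        sets = [StorySet([small, other]), StorySet([big, other])]
        finals = final_sets(sets)
        assert finals == [StorySet([big, other])]

    def test_chain_epn_maximal_unique(self):
        m = sd.fixture("toy_chain_assoc")
        best = epn_maximal_sets(enumerate_stories(m))
        assert len(best) == 1
        assert {s.epns for s in best[0]} == {frozenset("AB"), frozenset("CD")}
        assert best[0].total_epns == 4

    def test_worked_example_contains_fig6_pair(self, worked_example):
        stories = enumerate_stories(worked_example)
        pair = {frozenset({"a", "aP", "c"}), frozenset({"adp", "atp"})}
        assert any(pair <= {s.epns for s in ss}
                   for ss in maximal_valid_sets(stories))

    @pytest.mark.parametrize("name", ["toy_chain_assoc", "toy_transform_assoc",
                                      "worked_example", "at1ar_skeleton"])
    def test_implication_chain(self, name):
        """epn-maximal ⇒ final ⇒ maximally valid, on every fixture."""
        m = sd.fixture(name)
        stories = enumerate_stories(m)
        maximal = maximal_valid_sets(stories)
        finals = final_sets(maximal)
        best = epn_maximal_sets(maximal)
        assert all(f in maximal for f in finals)
        assert all(b in finals for b in best)
        for ss in maximal:
            assert ss.is_valid
            assert all(check_story(m, s.epns).ok for s in ss)

    def test_at1ar_receptor_vs_arrestin_alternatives(self):
        """The receptor story and the two β-arrestin stories are exclusive
        alternatives: no final set holds both, and both kinds occur."""
        m = sd.fixture("at1ar_skeleton")
        finals = final_sets(maximal_valid_sets(enumerate_stories(m)))
        receptor = frozenset({"HR", "HRp1", "HRp2", "HRb1", "HRb2"})
        arr1, arr2 = frozenset({"barr1", "HRb1"}), frozenset({"barr2", "HRb2"})
        with_receptor = [ss for ss in finals
                         if any(receptor <= s.epns for s in ss)]
        with_arrestins = [ss for ss in finals
                          if any(s.epns == arr1 for s in ss)
                          and any(s.epns == arr2 for s in ss)]
        assert with_receptor and with_arrestins
        assert not set(map(id, with_receptor)) & set(map(id, with_arrestins))

    def test_seeded_epn_maximal(self):
        m = sd.fixture("toy_chain_assoc")
        stories = enumerate_stories(m)
        seeded = epn_maximal_sets(stories, seeds=[Story(frozenset("ABD"))])
        assert len(seeded) == 1
        assert {s.epns for s in seeded[0]} == {frozenset("ABD")}


class TestConflictRelation:
    def test_worked_example_conflict(self, worked_example, worked_stories):
        """Both processes touch the phosphorylation story, so p # q."""
        rel = conflict_relation(worked_example, worked_stories)
        assert rel == frozenset({("p", "q")})

    def test_empty_story_set(self, worked_example):
        assert conflict_relation(worked_example, StorySet(())) == frozenset()

    def test_disjoint_stories_no_conflict(self):
        m = read_plain("epn a macromolecule\nepn b macromolecule\n"
                       "epn x macromolecule\nepn y macromolecule\n"
                       "process p process\nconsume p a\nproduce p b\n"
                       "process q process\nconsume q x\nproduce q y\n")
        ss = StorySet([Story({"a", "b"}), Story({"x", "y"})])
        assert conflict_relation(m, ss) == frozenset()

    def test_symmetric_irreflexive(self, worked_example, worked_stories):
        rel = conflict_relation(worked_example, worked_stories)
        assert all(p != q for p, q in rel)

    def test_invalid_set_rejected(self, worked_example):
        bad = StorySet([Story({"a", "aP"}), Story({"aP", "c"})])
        with pytest.raises(ValueError):
            conflict_relation(worked_example, bad)
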