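"""Automata-network encoding: automata, shortcut cases, transitions, exports."""

import itertools

import pytest
from lxml import etree

import sbgndyn as sd
from sbgndyn.encoding import (AutomataNetwork, GlobalState, LocalTransition,
                              add_local_transition, encode, export_pnml,
                              initial_global_state, parse_an, project_state,
                              serialize_an)
from sbgndyn.map_model import read_plain
from sbgndyn.stories import Story, StorySet


class TestEncodeGeneral:
    def test_worked_example_automata(self, general_an):
        """One Boolean automaton per EPN and per process: nine in total."""
        assert sorted(general_an.automata) == \
            ["a", "aP", "adp", "atp", "b", "c", "m", "p", "q"]
        assert all(st == ("0", "1") for st in general_an.automata.values())

    def test_activation_condition_includes_modulator_and_reactants(self, general_an):
        acts = [t for t in general_an.transitions
                if t.automaton == "p" and t.from_state == "0"]
        assert len(acts) == 1
        assert acts[0].condition == frozenset({("m", "1"), ("a", "1"), ("atp", "1")})

    def test_consumption_waits_for_all_products(self, general_an):
        cons = [t for t in general_an.transitions
                if t.automaton == "a" and t.from_state == "1"
                and ("p", "1") in t.condition]
        assert cons and cons[0].condition == \
            frozenset({("p", "1"), ("aP", "1"), ("adp", "1")})

    def test_deactivation_on_done(self, general_an):
        deact = [t for t in general_an.transitions
                 if t.automaton == "q" and t.from_state == "1"]
        assert deact[0].condition == frozenset({("c", "1")})

    def test_determinism(self, worked_example):
        assert encode(worked_example) == encode(worked_example)


class TestEncodeStories:
    def test_worked_example_story_automata(self, stories_an):
        assert sorted(stories_an.automata) == ["b", "m", "p", "q", "s", "t"]
        assert stories_an.automata["s"] == ("a", "aP", "c", "empty")
        assert stories_an.automata["t"] == ("adp", "atp", "empty")

    def test_conflicting_processes_guard_each_other(self, stories_an):
        """p # q, so each activation requires the other non-occurring."""
        act_p = next(t for t in stories_an.transitions
                     if t.automaton == "p" and t.from_state == "0")
        act_q = next(t for t in stories_an.transitions
                     if t.automaton == "q" and t.from_state == "0")
        assert ("q", "0") in act_p.condition
        assert ("p", "0") in act_q.condition
        assert act_p.condition == frozenset({("m", "1"), ("s", "a"),
                                             ("t", "atp"), ("q", "0")})

    def test_story_moves(self, stories_an):
        moves = {(t.automaton, t.from_state, t.to_state)
                 for t in stories_an.transitions if t.automaton in ("s", "t")}
        assert moves == {("s", "a", "aP"), ("s", "a", "c"), ("t", "atp", "adp")}

    def test_consumed_not_produced_story_goes_empty(self):
        # p consumes story member a and produces nothing in the story; with
        # a conflict present the general case applies and s moves to empty
        m = read_plain("epn a macromolecule\nepn b macromolecule\n"
                       "epn x macromolecule\n"
                       "process p process\nconsume p a\nproduce p x\n"
                       "process q process\nconsume q a\nproduce q b\n")
        ss = StorySet([Story({"a", "b"}, name="s")])
        an = encode(m, ss)
        assert any(t.automaton == "s" and t.from_state == "a"
                   and t.to_state == "empty" for t in an.transitions)
        done_p = next(t for t in an.transitions
                      if t.automaton == "p" and t.from_state == "1")
        assert ("s", "empty") in done_p.condition   # story consumed, not produced

    def test_invalid_story_set_rejected(self, worked_example):
        bad = StorySet([Story({"a", "aP"}), Story({"aP", "c"})])
        with pytest.raises(ValueError):
            encode(worked_example, bad)


class TestShortcuts:
    def test_single_consumption_shortcut(self):
        """Conflict-free single-reactant no-product process needs no automaton."""
        m = read_plain("epn e macromolecule\nprocess d process\nconsume d e\n")
        an = encode(m)
        assert sorted(an.automata) == ["e"]
        assert an.transitions == (LocalTransition("e", "1", "0"),)

    def test_sourceless_production_shortcut(self):
        m = read_plain("epn f macromolecule\nepn g macromolecule\n"
                       "process s process\nconsume s SOURCE\nproduce s f\n"
                       "produce s g\n")
        an = encode(m)
        assert sorted(an.automata) == ["f", "g"]
        # one independent transition per product, as specified
        assert set(an.transitions) == {LocalTransition("f", "0", "1"),
                                       LocalTransition("g", "0", "1")}

    def test_story_move_shortcut(self):
        m = read_plain("epn a macromolecule\nepn b macromolecule\n"
                       "process p process\nconsume p a\nproduce p b\n")
        ss = StorySet([Story({"a", "b"}, name="s")])
        an = encode(m, ss)
        assert sorted(an.automata) == ["s"]
        assert an.transitions == (LocalTransition("s", "a", "b"),)

    def test_no_shortcuts_keeps_process_automata(self):
        m = read_plain("epn e macromolecule\nprocess d process\nconsume d e\n")
        an = encode(m, shortcuts=False)
        assert sorted(an.automata) == ["d", "e"]

    def test_shortcut_denied_under_conflict(self, worked_example, worked_stories):
        # q is in(2)/out(1) and conflicts with p: both keep automata
        an = encode(worked_example, worked_stories)
        assert "p" in an.automata and "q" in an.automata


class TestInitialState:
    def test_general(self, general_an, worked_example):
        s = initial_global_state(general_an, worked_example, {"a", "atp", "b", "m"})
        assert s == GlobalState({"a": "1", "atp": "1", "b": "1", "m": "1",
                                 "aP": "0", "adp": "0", "c": "0",
                                 "p": "0", "q": "0"})

    def test_stories(self, stories_an, worked_example, worked_stories):
        s = initial_global_state(stories_an, worked_example,
                                 {"a", "atp", "b", "m"}, worked_stories)
        assert s == GlobalState({"s": "a", "t": "atp", "b": "1", "m": "1",
                                 "p": "0", "q": "0"})

    def test_two_story_members_conflict(self, stories_an, worked_example,
                                        worked_stories):
        with pytest.raises(ValueError, match="mutually exclusive"):
            initial_global_state(stories_an, worked_example, {"a", "aP"},
                                 worked_stories)

    def test_unlisted_story_starts_empty(self, stories_an, worked_example,
                                         worked_stories):
        s = initial_global_state(stories_an, worked_example, {"b"}, worked_stories)
        assert s["s"] == "empty" and s["t"] == "empty"


class TestProjection:
    def test_initial_states_correspond(self, worked_example, worked_stories,
                                       general_an, stories_an):
        si = initial_global_state(stories_an, worked_example,
                                  {"a", "atp", "b", "m"}, worked_stories)
        gi = initial_global_state(general_an, worked_example, {"a", "atp", "b", "m"})
        assert project_state(si, worked_example, worked_stories, general_an) == gi

    def test_empty_story_projects_all_absent(self, worked_example, worked_stories,
                                             general_an, stories_an):
        s = initial_global_state(stories_an, worked_example, set(), worked_stories)
        px = project_state(s, worked_example, worked_stories, general_an)
        assert px["a"] == px["aP"] == px["c"] == "0"

    def test_quiescent_states_project_into_general_stg(
            self, worked_example, worked_stories, general_an, stories_stg,
            general_stg):
        proc = ("p", "q")
        for x in stories_stg.nodes:
            if all(x[p] == "0" for p in proc):
                assert project_state(x, worked_example, worked_stories,
                                     general_an) in general_stg


class TestManualTransitions:
    def test_add_and_idempotence(self, general_an):
        t = LocalTransition("c", "0", "1", {("m", "1")})
        an2 = add_local_transition(general_an, t)
        assert len(an2.transitions) == len(general_an.transitions) + 1
        assert an2.provenance[t] == [("user", "manual")]
        an3 = add_local_transition(an2, t)
        assert len(an3.transitions) == len(an2.transitions)

    def test_unknown_state_rejected(self, general_an):
        with pytest.raises(ValueError):
            add_local_transition(general_an,
                                 LocalTransition("c", "0", "1", {("m", "7")}))

    def test_self_condition_rejected(self):
        with pytest.raises(ValueError):
            LocalTransition("c", "0", "1", {("c", "1")})


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

PNML_NS = {"p": "http://www.pnml.org/version-2009/grammar/pnml"}


def marking_graph(pnml_text):
    """Test-local 1-bounded Petri-net simulator: reachable markings.

    Parses places, transitions and arcs from the PNML document and fires
    transitions under 1-bounded semantics (self-loop pairs behave as read
    arcs).  Written independently of the network encoding.
    """
    root = etree.fromstring(pnml_text.encode())
    marked = {p.get("id") for p in root.findall(".//p:place", PNML_NS)
              if p.find(".//p:initialMarking", PNML_NS) is not None}
    pre, post = {}, {}
    for arc in root.findall(".//p:arc", PNML_NS):
        s, t = arc.get("source"), arc.get("target")
        if s.startswith("p__"):
            pre.setdefault(t, []).append(s)
        else:
            post.setdefault(s, []).append(t)
    tids = set(pre) | set(post)
    seen = {frozenset(marked)}
    frontier = [frozenset(marked)]
    edges = set()
    while frontier:
        nxt = []
        for mk in frontier:
            for t in tids:
                ins, outs = set(pre.get(t, [])), set(post.get(t, []))
                if not ins <= mk:
                    continue
                new = (mk - ins) | outs
                edges.add((mk, new))
                if new not in seen:
                    seen.add(new)
                    nxt.append(new)
        frontier = nxt
    return seen, edges


class TestExports:
    def test_three_automata_pnml_counts(self, three_automata_an):
        """3 automata with 3+2+2 states and 4 transitions give a net of
        7 places and 4 net transitions."""
        root = etree.fromstring(export_pnml(three_automata_an).encode())
        assert len(root.findall(".//p:place", PNML_NS)) == 7
        assert len(root.findall(".//p:transition", PNML_NS)) == 4

    def test_empty_an(self):
        root = etree.fromstring(export_pnml(AutomataNetwork({})).encode())
        assert not root.findall(".//p:place", PNML_NS)
        assert not root.findall(".//p:transition", PNML_NS)

    @pytest.mark.parametrize("style", ["selfloop", "test"])
    def test_read_arc_style_flagged(self, three_automata_an, style):
        root = etree.fromstring(export_pnml(three_automata_an, read_arcs=style).encode())
        meta = root.find(".//p:toolspecific", PNML_NS)
        assert meta.get("readArcStyle") == style

    def test_marking_graph_bijection_three_automata(self, three_automata_an, three_automata_initial):
        """Reachable markings of the exported net correspond one-to-one to
        the reachable global states of the network."""
        pnml = export_pnml(three_automata_an, initial=three_automata_initial)
        markings, _ = marking_graph(pnml)
        stg = sd.build_stg(three_automata_an, three_automata_initial)
        expected = {frozenset(f"p__{a}__{s}" for a, s in st.items())
                    for st in stg.nodes}
        assert markings == expected

    def test_marking_graph_bijection_worked_example(self, general_an,
                                                    worked_example):
        init = initial_global_state(general_an, worked_example,
                                    {"a", "atp", "b", "m"})
        markings, _ = marking_graph(export_pnml(general_an, initial=init))
        stg = sd.build_stg(general_an, init)
        expected = {frozenset(f"p__{a}__{s}" for a, s in st.items())
                    for st in stg.nodes}
        assert markings == expected

    def test_json_round_trip(self, general_an, stories_an):
        for an in (general_an, stories_an):
            assert parse_an(serialize_an(an)) == an

    def test_dot_renders_all_transitions(self, three_automata_an):
        dot = sd.an_to_dot(three_automata_an)
        assert dot.count("->") == len(three_automata_an.transitions)
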