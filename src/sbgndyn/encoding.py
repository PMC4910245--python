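"""Encoding of SBGN-PD maps into asynchronous automata networks.

An automata network is a triple (Σ, S, T): named finite automata, their
local states, and condition-guarded local transitions.  Both semantics
share one encoding; the general semantics is the special case of an
empty story set.

Automata: one Boolean automaton (states 0/1) per pool EPN outside every
story, one automaton per story with a state per member EPN plus the
*empty* state (the entity is absent), and one Boolean automaton per
process (0 non-occurring / 1 occurring) — except for three shortcut
cases where the process needs no automaton of its own: a conflict-free
process with no reactant pool, with a single reactant and no product, or
performing a simple change of story state (single reactant and single
product inside one story).

General-case transitions per process p, for each enabling condition
l in cond(p):

* activation      p0 -> p1 on l ∪ ready(p)
* production      f0 -> f1 on {p1}             (non-story products)
* consumption     e1 -> e0 on {p1} ∪ done(p)   (non-story reactants)
* story moves     s_e -> s_f on {p1} (consumed and produced in story S);
                  s_e -> s_empty when S is consumed but not produced;
                  s_empty -> s_f when p has no reactant pool and produces
                  into S
* de-activation   p1 -> p0 on done(p)

ready(p) gathers the present states of p's reactants (story or not), the
empty states of stories p produces into without consuming from (only
possible when p has no reactant pool), and q0 for every process q in
conflict with p.  done(p) gathers the present states of p's products and
the empty states of stories consumed-but-not-produced.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from lxml import etree

from .map_model import PDMap
from .modulation import conditions_of
from .stories import StorySet, conflict_relation, conflicts_of

logger = logging.getLogger(__name__)

Ref = tuple  # (automaton, local-state)


@dataclass(frozen=True)
class LocalTransition:
    automaton: str
    from_state: str
    to_state: str
    condition: frozenset = frozenset()   # refs into OTHER automata

    def __post_init__(self):
        object.__setattr__(self, "condition", frozenset(self.condition))
        if self.from_state == self.to_state:
            raise ValueError(f"degenerate transition on {self.automaton!r}")
        auts = [a for a, _ in self.condition]
        if self.automaton in auts:
            raise ValueError(
                f"transition on {self.automaton!r} conditions its own automaton")
        if len(set(auts)) < len(auts):
            raise ValueError("condition holds two local states of one automaton")

    def sort_key(self):
        return (self.automaton, self.from_state, self.to_state,
                tuple(sorted(self.condition)))

    def __str__(self):
        cond = ",".join(f"{a}={s}" for a, s in sorted(self.condition))
        return (f"{self.automaton}:{self.from_state}->{self.to_state}"
                + (f" [{cond}]" if cond else ""))


class GlobalState(Mapping):
    """One active local state per automaton; immutable and hashable."""

    __slots__ = ("_items", "_hash")

    def __init__(self, mapping):
        items = tuple(sorted(dict(mapping).items()))
        object.__setattr__(self, "_items", items)
        object.__setattr__(self, "_hash", hash(items))

    def __getitem__(self, key):
        for k, v in self._items:
            if k == key:
                return v
        raise KeyError(key)

    def __iter__(self):
        return (k for k, _ in self._items)

    def __len__(self):
        return len(self._items)

    def __hash__(self):
        return self._hash

    def __eq__(self, other):
        return isinstance(other, GlobalState) and self._items == other._items

    def replace(self, automaton, state) -> "GlobalState":
        return GlobalState({**dict(self._items), automaton: state})

    def contains_refs(self, refs: Iterable[Ref]) -> bool:
        d = dict(self._items)
        return all(d.get(a) == s for a, s in refs)

    def __str__(self):
        return "<" + ",".join(f"{a}_{s}" for a, s in self._items) + ">"

    __repr__ = __str__


class AutomataNetwork:
    """(Σ, S, T) with provenance tags mapping transitions to their origin."""

    def __init__(self, automata: Mapping[str, Iterable[str]],
                 transitions: Iterable[LocalTransition] = (),
                 provenance: Optional[Mapping] = None):
        self.automata = {name: tuple(states)
                         for name, states in sorted(dict(automata).items())}
        self.transitions = tuple(sorted(set(transitions),
                                        key=LocalTransition.sort_key))
        self.provenance = dict(provenance or {})
        self._check()
        self._by_automaton: dict = {}
        for t in self.transitions:
            self._by_automaton.setdefault((t.automaton, t.from_state), []).append(t)

    def _check(self):
        for t in self.transitions:
            states = self.automata.get(t.automaton)
            if states is None:
                raise ValueError(f"transition on unknown automaton {t.automaton!r}")
            for st in (t.from_state, t.to_state):
                if st not in states:
                    raise ValueError(f"unknown local state {t.automaton}_{st}")
            for a, s in t.condition:
                if s not in self.automata.get(a, ()):
                    raise ValueError(f"condition references unknown state {a}_{s}")

    def __eq__(self, other):
        return (isinstance(other, AutomataNetwork)
                and self.automata == other.automata
                and self.transitions == other.transitions)

    def outgoing(self, automaton: str, state: str) -> list:
        return self._by_automaton.get((automaton, state), [])

    def summary(self) -> str:
        return (f"{len(self.automata)} automata, "
                f"{sum(len(s) for s in self.automata.values())} local states, "
                f"{len(self.transitions)} local transitions")


# --------------------------------------------------------------------------
# Encoding
# --------------------------------------------------------------------------

def _sanitize(aut: str, from_state: str, condition: Iterable[Ref]):
    """Drop self-references implied by the origin state; reject contradictions.

    Returns the cleaned condition, or None if the transition can never
    fire (the condition demands a different state of its own automaton,
    or two states of one automaton).
    """
    cond = set(condition)
    cleaned = set()
    for a, s in cond:
        if a == aut:
            if s != from_state:
                return None
            continue  # implied by the origin local state
        cleaned.add((a, s))
    auts = [a for a, _ in cleaned]
    if len(set(auts)) < len(auts):
        return None
    return frozenset(cleaned)


def encode(pdmap: PDMap, stories: Optional[StorySet] = None,
           shortcuts: bool = True, strict_formula: bool = False) -> AutomataNetwork:
    """Build the automata network of a map under either semantics.

    An empty (or None) story set yields the general semantics.  With
    ``shortcuts`` disabled every process gets an automaton, which keeps
    the state space aligned with the rule-based interpreter.
    """
    stories = stories or StorySet(())
    if not stories.is_valid:
        raise ValueError("story set is not valid (stories intersect)")
    union = stories.union_epns
    for e in union:
        node = pdmap.epns.get(e)
        if node is None:
            raise ValueError(f"story references unknown EPN {e!r}")
        if node.is_source_sink:
            raise ValueError(f"story contains source/sink EPN {e!r}")
    conflicts = conflict_relation(pdmap, stories)

    automata: dict = {}
    for e in pdmap.pool_epns():
        if e not in union:
            automata[e] = ("0", "1")
    for s in stories:
        automata[s.id] = tuple(sorted(s.epns)) + ("empty",)

    def story_of(e):
        return stories.story_of(e)

    def is_shortcut(pid) -> bool:
        if not shortcuts or conflicts_of(conflicts, pid):
            return False
        inp, outp = pdmap.in_(pid), pdmap.out(pid)
        if not inp:
            return True
        if len(inp) == 1:
            if not outp:
                return True
            if len(outp) == 1:
                (e,), (f,) = tuple(inp), tuple(outp)
                se, sf = story_of(e), story_of(f)
                return se is not None and se is sf
        return False

    shortcut_pids = {pid for pid in pdmap.processes if is_shortcut(pid)}
    for pid in pdmap.processes:
        if pid not in shortcut_pids:
            automata[pid] = ("0", "1")

    transitions: list = []
    provenance: dict = {}

    def add(aut, frm, to, cond, pid, tag):
        cleaned = _sanitize(aut, frm, cond)
        if cleaned is None:
            logger.debug("dropped unsatisfiable %s transition of %s", tag, pid)
            return
        t = LocalTransition(aut, frm, to, cleaned)
        transitions.append(t)
        provenance.setdefault(t, []).append((pid, tag))

    for pid in sorted(pdmap.processes):
        conds = conditions_of(pdmap, pid, stories, strict_formula=strict_formula)
        inp, outp = pdmap.in_(pid), pdmap.out(pid)
        if pid in shortcut_pids:
            if not inp:
                for ell in conds:
                    for f in sorted(outp):
                        sf = story_of(f)
                        if sf is not None:
                            add(sf.id, "empty", f, ell, pid, "shortcut-production")
                        else:
                            add(f, "0", "1", ell, pid, "shortcut-production")
            elif not outp:
                (e,) = tuple(inp)
                se = story_of(e)
                for ell in conds:
                    if se is not None:
                        add(se.id, e, "empty", ell, pid, "shortcut-consumption")
                    else:
                        add(e, "1", "0", ell, pid, "shortcut-consumption")
            else:
                (e,), (f,) = tuple(inp), tuple(outp)
                s = story_of(e)
                for ell in conds:
                    add(s.id, e, f, ell, pid, "shortcut-story-move")
            continue

        # general case
        ready = set()
        done = set()
        for e in sorted(inp):
            s = story_of(e)
            ready.add((s.id, e) if s is not None else (e, "1"))
        for f in sorted(outp):
            s = story_of(f)
            done.add((s.id, f) if s is not None else (f, "1"))
        produced_stories = {story_of(f) for f in outp if story_of(f) is not None}
        consumed_stories = {story_of(e) for e in inp if story_of(e) is not None}
        if not inp:
            for s in produced_stories:
                ready.add((s.id, "empty"))
        else:
            # story constraint (ii) forbids producing into a story without
            # consuming from it when the process has a reactant pool
            assert produced_stories <= consumed_stories, \
                f"process {pid} produces into a story it does not consume from"
        for s in consumed_stories - produced_stories:
            done.add((s.id, "empty"))
        for q in conflicts_of(conflicts, pid):
            if q in automata:   # conflicting process always has an automaton
                ready.add((q, "0"))

        for ell in conds:
            add(pid, "0", "1", set(ell) | ready, pid, "process activation")
        for f in sorted(outp - union):
            add(f, "0", "1", {(pid, "1")}, pid, "production")
        for e in sorted(inp - union):
            add(e, "1", "0", {(pid, "1")} | done, pid, "consumption")
        for s in stories:
            se = inp & s.epns
            if se:
                (e,) = tuple(se)
                sf = outp & s.epns
                if sf:
                    (f,) = tuple(sf)
                    add(s.id, e, f, {(pid, "1")}, pid, "stories")
                else:
                    add(s.id, e, "empty", {(pid, "1")}, pid, "stories")
            elif not inp:
                for f in sorted(outp & s.epns):
                    add(s.id, "empty", f, {(pid, "1")}, pid, "stories")
        add(pid, "1", "0", done, pid, "process de-activation")

    return AutomataNetwork(automata, transitions, provenance)


def initial_global_state(an: AutomataNetwork, pdmap: PDMap,
                         present_epns: Iterable[str],
                         stories: Optional[StorySet] = None) -> GlobalState:
    """Encode a set of initially present EPNs into a global state.

    Two present EPNs of one story contradict mutual exclusivity and raise
    ValueError.  Story automata without a listed member start empty;
    process automata start non-occurring.
    """
    stories = stories or StorySet(())
    present = set(present_epns)
    unknown = present - set(pdmap.epns)
    if unknown:
        raise KeyError(f"unknown EPN ids in initial state: {sorted(unknown)}")
    assignment = {}
    for s in stories:
        listed = sorted(present & s.epns)
        if len(listed) > 1:
            raise ValueError(
                f"initial state lists {listed} which all belong to story {s.id}: "
                "EPNs of a story are mutually exclusive")
        assignment[s.id] = listed[0] if listed else "empty"
    for name, states in an.automata.items():
        if name in assignment:
            continue
        if name in pdmap.epns:
            assignment[name] = "1" if name in present else "0"
        else:
            assignment[name] = "0"   # process automaton
    return GlobalState(assignment)


def project_state(state: GlobalState, pdmap: PDMap, stories: StorySet,
                  general_an: AutomataNetwork) -> GlobalState:
    """[x]: the general-semantics state matching a stories-semantics state.

    An EPN inside a story is present exactly when its story automaton sits
    at its state.  Process automata are copied when both encodings have
    them; a process without an automaton in the stories encoding is
    mapped to non-occurring.
    """
    assignment = {}
    story_states = {}
    for s in stories:
        try:
            story_states[s] = state[s.id]
        except KeyError as exc:
            raise ValueError(f"state lacks story automaton {s.id!r}") from exc
    for name in general_an.automata:
        if name in pdmap.epns:
            s = stories.story_of(name)
            if s is not None:
                assignment[name] = "1" if story_states[s] == name else "0"
            else:
                try:
                    assignment[name] = state[name]
                except KeyError as exc:
                    raise ValueError(f"state lacks automaton {name!r}") from exc
        else:
            assignment[name] = state.get(name, "0")
    return GlobalState(assignment)


def add_local_transition(an: AutomataNetwork,
                         transition: LocalTransition) -> AutomataNetwork:
    """Return the network augmented with a manual transition (idempotent).

    Used e.g. to model transcriptional effects: a transition taking an
    entity from absent to present, guarded by the states under which its
    transcription is up-regulated.
    """
    states = an.automata.get(transition.automaton)
    if states is None:
        raise ValueError(f"unknown automaton {transition.automaton!r}")
    for st in (transition.from_state, transition.to_state):
        if st not in states:
            raise ValueError(f"unknown local state {transition.automaton}_{st}")
    for a, s in transition.condition:
        if s not in an.automata.get(a, ()):
            raise ValueError(f"condition references unknown state {a}_{s}")
    provenance = dict(an.provenance)
    provenance.setdefault(transition, []).append(("user", "manual"))
    return AutomataNetwork(an.automata,
                           an.transitions + (transition,), provenance)


# --------------------------------------------------------------------------
# Exports
# --------------------------------------------------------------------------

_PNML_NS = "http://www.pnml.org/version-2009/grammar/pnml"


def export_pnml(an: AutomataNetwork, initial: Optional[GlobalState] = None,
                read_arcs: str = "selfloop") -> str:
    """Export as a 1-bounded place/transition net.

    One place per local state (marked iff active in ``initial``), one net
    transition per local transition with a single input and output arc,
    and the condition's local states attached either as ``test`` arcs
    (``read_arcs='test'``, a dialect extension flagged in the net
    metadata) or as self-loop input/output pairs (default, plain PNML).
    """
    if read_arcs not in ("selfloop", "test"):
        raise ValueError("read_arcs must be 'selfloop' or 'test'")
    root = etree.Element(f"{{{_PNML_NS}}}pnml")
    net = etree.SubElement(root, f"{{{_PNML_NS}}}net",
                           id="an", type="http://www.pnml.org/version-2009/grammar/ptnet")
    page = etree.SubElement(net, f"{{{_PNML_NS}}}page", id="page0")
    meta = etree.SubElement(net, f"{{{_PNML_NS}}}toolspecific",
                            tool="sbgndyn", version="1")
    meta.set("readArcStyle", read_arcs)

    def place_id(aut, st):
        return f"p__{aut}__{st}"

    for aut, states in an.automata.items():
        for st in states:
            pl = etree.SubElement(page, f"{{{_PNML_NS}}}place", id=place_id(aut, st))
            name = etree.SubElement(pl, f"{{{_PNML_NS}}}name")
            etree.SubElement(name, f"{{{_PNML_NS}}}text").text = f"{aut}_{st}"
            if initial is not None and initial[aut] == st:
                mk = etree.SubElement(pl, f"{{{_PNML_NS}}}initialMarking")
                etree.SubElement(mk, f"{{{_PNML_NS}}}text").text = "1"

    arc_n = 0

    def arc(src, tgt, kind=None):
        nonlocal arc_n
        arc_n += 1
        a = etree.SubElement(page, f"{{{_PNML_NS}}}arc",
                             id=f"a{arc_n}", source=src, target=tgt)
        if kind:
            t = etree.SubElement(a, f"{{{_PNML_NS}}}type")
            t.set("value", kind)

    for i, tr in enumerate(an.transitions):
        tid = f"t{i}"
        t = etree.SubElement(page, f"{{{_PNML_NS}}}transition", id=tid)
        name = etree.SubElement(t, f"{{{_PNML_NS}}}name")
        etree.SubElement(name, f"{{{_PNML_NS}}}text").text = str(tr)
        arc(place_id(tr.automaton, tr.from_state), tid)
        arc(tid, place_id(tr.automaton, tr.to_state))
        for a_, s_ in sorted(tr.condition):
            if read_arcs == "test":
                arc(place_id(a_, s_), tid, kind="read")
            else:
                arc(place_id(a_, s_), tid)
                arc(tid, place_id(a_, s_))
    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode()


def serialize_an(an: AutomataNetwork) -> str:
    """Lossless JSON serialization (automata, transitions, provenance)."""
    data = {
        "automata": {a: list(st) for a, st in an.automata.items()},
        "transitions": [
            {"automaton": t.automaton, "from": t.from_state, "to": t.to_state,
             "condition": sorted([a, s] for a, s in t.condition),
             "provenance": an.provenance.get(t, [])}
            for t in an.transitions],
    }
    return json.dumps(data, indent=2, sort_keys=True)


def parse_an(document: str) -> AutomataNetwork:
    data = json.loads(document)
    transitions, provenance = [], {}
    for td in data["transitions"]:
        t = LocalTransition(td["automaton"], td["from"], td["to"],
                            frozenset((a, s) for a, s in td["condition"]))
        transitions.append(t)
        if td.get("provenance"):
            provenance[t] = [tuple(p) for p in td["provenance"]]
    return AutomataNetwork(data["automata"], transitions, provenance)


def an_to_dot(an: AutomataNetwork) -> str:
    """DOT rendering: one cluster per automaton, labelled guarded edges."""
    lines = ["digraph an {", "  compound=true;"]
    for i, (aut, states) in enumerate(an.automata.items()):
        lines.append(f'  subgraph cluster_{i} {{ label="{aut}";')
        for st in states:
            lines.append(f'    "{aut}__{st}" [label="{st}"];')
        lines.append("  }")
    for t in an.transitions:
        cond = ", ".join(f"{a}_{s}" for a, s in sorted(t.condition))
        lines.append(f'  "{t.automaton}__{t.from_state}" -> '
                     f'"{t.automaton}__{t.to_state}" [label="{cond}"];')
    lines.append("}")
    return "\n".join(lines)
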