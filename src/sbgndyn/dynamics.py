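"""Asynchronous dynamics of automata networks.

One local transition fires at a time: a transition a_i -> a_j with
condition l applies in a global state s iff a is at a_i in s and every
local state of l is active in s; the successor replaces a_i with a_j.
Exhaustive exploration from an initial state yields the state transition
graph (STG); its terminal strongly connected components are the
attractors (point attractors when singletons).  Phases are named marker
sets over the map; a phase is reachable when some reachable state shows
one of its markers present.

``oracle_successors`` interprets the general-semantics transition rules
directly on the map, independently of the automata-network encoding; it
serves as a cross-implementation oracle in the test suite.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Optional

import networkx as nx

from .encoding import AutomataNetwork, GlobalState, LocalTransition
from .map_model import PDMap
from .modulation import logic_of, NotTainted
from .stories import StorySet

DEFAULT_CAP = 1_000_000


class BoundedExplorationError(RuntimeError):
    """The reachable state space exceeded the requested cap."""

    def __init__(self, cap: int, frontier: int):
        super().__init__(
            f"state exploration exceeded cap of {cap} states "
            f"(frontier held {frontier} states); raise the cap to resume")
        self.cap = cap
        self.frontier = frontier


# --------------------------------------------------------------------------
# Successors and state transition graph
# --------------------------------------------------------------------------

def successors(an: AutomataNetwork, state: GlobalState) -> list:
    """All asynchronous successors of a state with their firing transitions."""
    missing = set(an.automata) - set(state)
    if missing:
        raise ValueError(f"state misses automata {sorted(missing)}")
    out = []
    for aut in an.automata:
        for t in an.outgoing(aut, state[aut]):
            if state.contains_refs(t.condition):
                out.append((state.replace(aut, t.to_state), t))
    return out


def build_stg(an: AutomataNetwork, initial: GlobalState,
              cap: int = DEFAULT_CAP,
              rng: Optional[random.Random] = None) -> nx.DiGraph:
    """Breadth-first construction of the full STG from an initial state.

    ``rng`` randomizes the exploration order (the resulting graph is the
    same; used by the order-independence property test).  Raises
    BoundedExplorationError when the state count would exceed ``cap``.
    """
    g = nx.DiGraph(initial=initial)
    g.add_node(initial)
    frontier = [initial]
    seen = {initial}
    while frontier:
        if rng is not None:
            rng.shuffle(frontier)
        nxt = []
        for state in frontier:
            for succ, t in successors(an, state):
                if succ not in seen:
                    if len(seen) >= cap:
                        raise BoundedExplorationError(cap, len(frontier) + len(nxt))
                    seen.add(succ)
                    nxt.append(succ)
                g.add_edge(state, succ, transition=t)
        frontier = nxt
    return g


# --------------------------------------------------------------------------
# Attractors
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Attractor:
    states: frozenset
    kind: str   # "point" | "cyclic"

    def __len__(self):
        return len(self.states)


def attractors(stg: nx.DiGraph) -> list:
    """Terminal strongly connected components, deterministically ordered."""
    cond = nx.condensation(stg)
    result = []
    for scc_id in cond.nodes:
        if cond.out_degree(scc_id) == 0:
            members = frozenset(cond.nodes[scc_id]["members"])
            result.append(Attractor(members,
                                    "point" if len(members) == 1 else "cyclic"))
    return sorted(result, key=lambda a: tuple(sorted(str(s) for s in a.states)))


# --------------------------------------------------------------------------
# Reachability
# --------------------------------------------------------------------------

def is_reachable(an: AutomataNetwork, initial: GlobalState,
                 goal: Iterable, cap: int = DEFAULT_CAP) -> bool:
    """Whether some reachable state contains all goal local states.

    The goal is a partial state: a set of (automaton, state) references,
    all of which must be active simultaneously.  On-the-fly search; the
    full STG is not retained.
    """
    goal = frozenset(goal)
    for a, s in goal:
        if s not in an.automata.get(a, ()):
            raise ValueError(f"goal references unknown local state {a}_{s}")
    by_aut = {}
    for a, s in goal:
        if a in by_aut and by_aut[a] != s:
            return False   # two states of one automaton can never coexist
        by_aut[a] = s
    seen = {initial}
    frontier = [initial]
    if initial.contains_refs(goal):
        return True
    while frontier:
        nxt = []
        for state in frontier:
            for succ, _ in successors(an, state):
                if succ in seen:
                    continue
                if succ.contains_refs(goal):
                    return True
                if len(seen) >= cap:
                    raise BoundedExplorationError(cap, len(frontier) + len(nxt))
                seen.add(succ)
                nxt.append(succ)
        frontier = nxt
    return False


# --------------------------------------------------------------------------
# Phases and markers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Phase:
    name: str
    markers: frozenset

    def __post_init__(self):
        object.__setattr__(self, "markers", frozenset(self.markers))


def marker_ref(marker: str, stories: Optional[StorySet]):
    """The local state whose activity means 'marker present'."""
    s = stories.story_of(marker) if stories is not None else None
    return (s.id, marker) if s is not None else (marker, "1")


def phase_reachable(an: AutomataNetwork, initial: GlobalState, phase: Phase,
                    stories: Optional[StorySet] = None,
                    cap: int = DEFAULT_CAP) -> bool:
    """A phase is reached when any one of its markers becomes present."""
    return any(is_reachable(an, initial, {marker_ref(m, stories)}, cap=cap)
               for m in sorted(phase.markers))


def phases_simultaneously_reachable(an: AutomataNetwork, initial: GlobalState,
                                    phase_p: Phase, phase_q: Phase,
                                    stories: Optional[StorySet] = None,
                                    cap: int = DEFAULT_CAP) -> bool:
    """Whether some reachable state shows a marker of each phase at once."""
    for e in sorted(phase_p.markers):
        for f in sorted(phase_q.markers):
            refs = {marker_ref(e, stories), marker_ref(f, stories)}
            if is_reachable(an, initial, refs, cap=cap):
                return True
    return False


def disable_markers(an: AutomataNetwork, markers: Iterable[str],
                    stories: Optional[StorySet] = None) -> AutomataNetwork:
    """Remove every transition entering or leaving a marker's present state.

    For a story member the present state is its story-automaton state, so
    disabling also blocks story traversal through that state — a stronger
    cut than for a Boolean EPN.  Conditions referencing the state are
    kept: they simply never fire once the state is unreachable.
    """
    cut = {marker_ref(m, stories) for m in markers}
    for a, s in cut:
        if s not in an.automata.get(a, ()):
            raise ValueError(f"unknown marker state {a}_{s}")
    kept = [t for t in an.transitions
            if (t.automaton, t.from_state) not in cut
            and (t.automaton, t.to_state) not in cut]
    provenance = {t: p for t, p in an.provenance.items() if t in set(kept)}
    return AutomataNetwork(an.automata, kept, provenance)


# --------------------------------------------------------------------------
# Rule-based oracle for the general semantics
# --------------------------------------------------------------------------

def _mod_satisfied(pdmap: PDMap, pid: str, present: set) -> bool:
    """Permissive modulation rule evaluated directly on an EPN assignment."""

    def usable(origins):
        out = []
        for n in origins:
            f = logic_of(pdmap, n)
            if not isinstance(f, NotTainted):
                out.append(f)
        return out

    req = usable(pdmap.req(pid))
    act = usable(pdmap.act(pid))
    inh = usable(pdmap.inh(pid))
    if not all(f.evaluate(present) for f in req):
        return False
    if not act and not inh:
        return True
    return (any(f.evaluate(present) for f in act)
            or any(not f.evaluate(present) for f in inh))


def oracle_successors(pdmap: PDMap, state: dict) -> set:
    """General-semantics successors straight from the four transition rules.

    ``state`` maps every pool EPN to present/absent and every process to
    occurring/non-occurring (booleans).  Exactly one entity flips per
    successor:

    1. p starts occurring iff its non-source reactants are all present
       and its modulation rule is satisfied;
    2. p stops occurring iff its non-sink products are all present;
    3. an EPN becomes present iff some occurring process produces it;
    4. an EPN becomes absent iff some occurring process consumes it and
       every product of that process is present.

    Implemented on the map only — no automata-network machinery.
    """
    present = {e for e in pdmap.pool_epns() if state[e]}
    occurring = {p for p in pdmap.processes if state[p]}
    result = set()

    def flipped(key):
        s = dict(state)
        s[key] = not s[key]
        return frozenset(s.items())

    for pid in pdmap.processes:
        if not state[pid]:
            if pdmap.in_(pid) <= present and _mod_satisfied(pdmap, pid, present):
                result.add(flipped(pid))
        else:
            if pdmap.out(pid) <= present:
                result.add(flipped(pid))
    for e in pdmap.pool_epns():
        if not state[e]:
            if any(e in pdmap.out(p) for p in occurring):
                result.add(flipped(e))
        else:
            if any(e in pdmap.in_(p) and pdmap.out(p) <= present
                   for p in occurring):
                result.add(flipped(e))
    return result
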