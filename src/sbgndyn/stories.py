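"""Stories: sets of EPNs representing mutually exclusive states of one entity.

A story gathers the EPNs that stand for the different physical states
(unmodified, phosphorylated, in complex, ...) of a single molecular
entity.  On a given map a story must satisfy:

(i)   any two of its EPNs are joined by a flux-arc path whose EPNs all
      belong to the story;
(ii)  if a process produces a story EPN, at least one of its reactants
      belongs to the story (or the process has no reactant pool at all,
      i.e. consumes only a source);
(iii) no process consumes two story EPNs;
(iv)  no process produces two story EPNs;
(v)   optionally, all story EPNs share one label (their own label or,
      for complexes, a component label).

Sources and sinks are excluded from stories.  A collection of stories is
*valid* when pairwise disjoint; among valid sets, *final* sets are the
undominated ones and *epn-maximal* sets maximize the total EPN count.
Processes touching a common story are in *conflict* (#) and may not
occur simultaneously.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

from .map_model import PDMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Story:
    epns: frozenset
    name: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "epns", frozenset(self.epns))

    @property
    def id(self) -> str:
        """Deterministic identifier: explicit name or a digest of the EPN ids."""
        if self.name:
            return self.name
        digest = hashlib.sha1("|".join(sorted(self.epns)).encode()).hexdigest()
        return f"story-{digest[:8]}"

    def __len__(self):
        return len(self.epns)

    def __contains__(self, epn):
        return epn in self.epns

    def __iter__(self):
        return iter(sorted(self.epns))


class StorySet:
    """A collection of stories with derived accessors; valid iff pairwise disjoint."""

    def __init__(self, stories: Iterable[Story] = ()):
        self.stories = tuple(sorted(
            (s if isinstance(s, Story) else Story(frozenset(s)) for s in stories),
            key=lambda s: s.id))
        self._by_epn = {}
        for s in self.stories:
            for e in s.epns:
                self._by_epn.setdefault(e, s)

    def __iter__(self):
        return iter(self.stories)

    def __len__(self):
        return len(self.stories)

    def __eq__(self, other):
        return isinstance(other, StorySet) and \
            {s.epns for s in self} == {s.epns for s in other}

    def __hash__(self):
        return hash(frozenset(s.epns for s in self.stories))

    def __repr__(self):
        return "StorySet(%s)" % ", ".join(
            "{" + ",".join(s) + "}" for s in self.stories)

    @property
    def is_valid(self) -> bool:
        return sum(len(s) for s in self.stories) == len(self.union_epns)

    @property
    def union_epns(self) -> frozenset:
        return frozenset().union(*(s.epns for s in self.stories)) \
            if self.stories else frozenset()

    @property
    def total_epns(self) -> int:
        return len(self.union_epns)

    def story_of(self, epn: str) -> Optional[Story]:
        return self._by_epn.get(epn)

    def of_process(self, pdmap: PDMap, pid: str) -> tuple:
        """S(p): the stories whose EPNs p consumes or produces."""
        touched = pdmap.in_(pid) | pdmap.out(pid)
        return tuple(s for s in self.stories if s.epns & touched)

    def to_json(self, **flags) -> str:
        return json.dumps({
            "stories": [{"epns": sorted(s.epns)} for s in self.stories],
            "flags": {"valid": self.is_valid, **flags}}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "StorySet":
        data = json.loads(text)
        return cls(Story(frozenset(s["epns"])) for s in data["stories"])


# --------------------------------------------------------------------------
# Story constraint checking
# --------------------------------------------------------------------------

def _share_graph(pdmap: PDMap, nodes: Iterable[str]) -> nx.Graph:
    """EPNs joined iff they are reactant-or-product of a common process."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    pool = set(g.nodes)
    for pid in pdmap.processes:
        members = sorted((pdmap.in_(pid) | pdmap.out(pid)) & pool)
        for a, b in itertools.combinations(members, 2):
            g.add_edge(a, b)
    return g


@dataclass(frozen=True)
class StoryVerdict:
    ok: bool
    violations: frozenset   # subset of {i, ii, iii, iv, v,
    #                         contains-source-or-sink, too-small}
    notes: tuple = ()


def check_story(pdmap: PDMap, epns: Iterable[str], label_constraint: bool = False,
                min_size: int = 2) -> StoryVerdict:
    """Check constraints (i)-(iv) (and (v) if asked) for a candidate EPN set."""
    epns = frozenset(epns)
    unknown = epns - set(pdmap.epns)
    if unknown:
        raise KeyError(f"unknown EPN ids: {sorted(unknown)}")
    violations = set()
    notes = []
    if any(pdmap.epns[e].is_source_sink for e in epns):
        violations.add("contains-source-or-sink")
    if len(epns) < min_size:
        violations.add("too-small")
    members = epns - {e for e in epns if pdmap.epns[e].is_source_sink}
    if len(members) >= 2:
        sub = _share_graph(pdmap, members)
        if not nx.is_connected(sub):
            violations.add("i")
    for pid in pdmap.processes:
        inp, outp = pdmap.in_(pid), pdmap.out(pid)
        if outp & members and inp and not (inp & members):
            violations.add("ii")
        if len(inp & members) > 1:
            violations.add("iii")
        if len(outp & members) > 1:
            violations.add("iv")
    if label_constraint and members:
        if _shared_label(pdmap, members) is None:
            violations.add("v")
    # Advisory only (not enforced): a story holding both a reactant and the
    # sole stimulator of one process would block that process for good.
    for pid in pdmap.processes:
        act = [o for o in pdmap.act(pid) if o in pdmap.epns]
        if (len(act) == 1 and act[0] in members
                and pdmap.in_(pid) & (members - {act[0]})):
            note = (f"story contains reactant and sole stimulator of {pid}; "
                    "the process can never occur under the stories semantics")
            notes.append(note)
            logger.warning("%s", note)
    return StoryVerdict(not violations, frozenset(violations), tuple(notes))


def _shared_label(pdmap: PDMap, members) -> Optional[str]:
    candidates = None
    for e in members:
        node = pdmap.epns[e]
        labels = {node.label} | set(node.component_labels)
        labels.discard("")
        candidates = labels if candidates is None else candidates & labels
        if not candidates:
            return None
    return sorted(candidates)[0] if candidates else None


# --------------------------------------------------------------------------
# Story enumeration
# --------------------------------------------------------------------------

def enumerate_stories(pdmap: PDMap, min_size: int = 2, max_size: Optional[int] = None,
                      label_constraint: bool = False,
                      seeds: Optional[Sequence] = None) -> list:
    """All stories of the map within the size bounds.

    Enumerates connected subsets of the share-a-process graph (constraint
    (i) holds by construction), pruning on the monotone constraints (iii)
    and (iv) while growing, and filtering on (ii), (v) and size at the
    end.  ``seeds`` are EPN sets that must themselves be stories; a seed
    violating the constraints raises ValueError.
    """
    eligible = [e for e in pdmap.pool_epns()]
    graph = _share_graph(pdmap, eligible)
    if max_size is None:
        max_size = len(eligible)

    in_sets = [pdmap.in_(pid) for pid in pdmap.processes]
    out_sets = [pdmap.out(pid) for pid in pdmap.processes]

    def monotone_ok(sub: frozenset) -> bool:
        return all(len(s & sub) <= 1 for s in in_sets) and \
            all(len(s & sub) <= 1 for s in out_sets)

    found = set()
    order = {e: i for i, e in enumerate(sorted(eligible))}

    def grow(current: set, candidates: set, banned: set):
        if min_size <= len(current) <= max_size:
            found.add(frozenset(current))
        if len(current) >= max_size:
            return
        local_banned = set(banned)
        for u in sorted(candidates - local_banned):
            new = current | {u}
            if monotone_ok(frozenset(new)):
                new_cands = (candidates | set(graph.adj[u])) - new
                grow(new, new_cands, set(local_banned))
            local_banned.add(u)

    for anchor in sorted(eligible):
        banned = {e for e in eligible if order[e] < order[anchor]}
        grow({anchor}, set(graph.adj[anchor]) - banned, banned)

    stories = []
    for sub in sorted(found, key=lambda s: tuple(sorted(s))):
        verdict = check_story(pdmap, sub, label_constraint=label_constraint,
                              min_size=min_size)
        if verdict.ok:
            stories.append(Story(sub))

    if seeds:
        story_sets = {s.epns for s in stories}
        for seed in seeds:
            seed = frozenset(seed)
            verdict = check_story(pdmap, seed, label_constraint=label_constraint,
                                  min_size=min(min_size, len(seed)))
            if not verdict.ok:
                raise ValueError(
                    f"seed {sorted(seed)} is not a story; violated constraints: "
                    f"{sorted(verdict.violations)}")
            if seed not in story_sets:
                stories.append(Story(seed))
        stories.sort(key=lambda s: tuple(sorted(s.epns)))
    return stories


# --------------------------------------------------------------------------
# Valid / final / epn-maximal story sets
# --------------------------------------------------------------------------

def _intersection_graph(stories: Sequence[Story]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(len(stories)))
    for i, j in itertools.combinations(range(len(stories)), 2):
        if stories[i].epns & stories[j].epns:
            g.add_edge(i, j)
    return g

def maximal_valid_sets(stories: Sequence[Story]) -> list:
    """All inclusion-maximal pairwise-disjoint collections of the given stories.

    These are the maximal independent sets of the story-intersection graph,
    enumerated as maximal cliques of its complement.
    """
    stories = list(stories)
    if not stories:
        return []
    comp = nx.complement(_intersection_graph(stories))
    sets = [StorySet(stories[i] for i in clique)
            for clique in nx.find_cliques(comp)]
    return sorted(sets, key=lambda ss: tuple(tuple(sorted(s.epns)) for s in ss))


def _dominates(candidate: StorySet, other: StorySet) -> bool:
    """candidate != other and every story of `other` has a superset in candidate."""
    if candidate == other:
        return False
    return all(any(t.epns <= c.epns for c in candidate) for t in other)


def final_sets(valid_sets: Sequence[StorySet]) -> list:
    """Filter out valid sets dominated story-wise by another candidate.

    With ``valid_sets`` the full list of inclusion-maximal valid sets this
    yields exactly the final sets (a dominating valid set always extends
    to a dominating maximal one).
    """
    return [s for s in valid_sets
            if not any(_dominates(other, s) for other in valid_sets)]


def epn_maximal_sets(stories_or_sets, seeds: Optional[Sequence[Story]] = None) -> list:
    """All valid sets attaining the maximum total number of EPNs.

    Accepts either a list of stories (maximal valid sets are enumerated
    first) or a pre-computed list of StorySet candidates.  Since every
    valid set extends to an inclusion-maximal one without losing EPNs,
    the optimum — with all ties — is found among the maximal sets.  With
    ``seeds``, only sets containing every seed story compete.
    """
    items = list(stories_or_sets)
    if items and isinstance(items[0], StorySet):
        candidates = items
    else:
        candidates = maximal_valid_sets(items)
    if seeds:
        seed_epns = [frozenset(s.epns if isinstance(s, Story) else s) for s in seeds]
        candidates = [c for c in candidates
                      if all(any(se == st.epns for st in c) for se in seed_epns)]
    if not candidates:
        return []
    best = max(c.total_epns for c in candidates)
    return [c for c in candidates if c.total_epns == best]


# --------------------------------------------------------------------------
# Process conflicts
# --------------------------------------------------------------------------

def conflict_relation(pdmap: PDMap, stories: StorySet) -> frozenset:
    """#: unordered pairs of distinct processes acting on a common story."""
    if not stories.is_valid:
        raise ValueError("story set is not valid (stories intersect)")
    touched = {pid: set(stories.of_process(pdmap, pid)) for pid in pdmap.processes}
    pairs = set()
    for p, q in itertools.combinations(sorted(pdmap.processes), 2):
        if touched[p] & touched[q]:
            pairs.add((p, q))
    return frozenset(pairs)


def conflicts_of(relation: frozenset, pid: str) -> list:
    return sorted({b if a == pid else a for a, b in relation if pid in (a, b)})
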