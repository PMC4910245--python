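"""Boolean logic of process modulations.

Each modulation origin n (an EPN or a logical-operator tree) gets a
satisfaction formula logic(n) over EPN-presence literals.  A process p
occurs permissively: all necessary stimulations must hold, and — if the
process carries any stimulation/catalysis or inhibition — at least one
stimulation must hold or at least one inhibition must fail.  The formula
mod(p) is put into disjunctive normal form and expanded into cond(p):
the sets of automata local states that enable the process.

Generic ``modulation``-class arcs (unknown effect) and arcs whose origin
formula routes through a NOT operator (no dynamical meaning) are dropped
before building the formula.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional

from .map_model import PDMap

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Formula tree
# --------------------------------------------------------------------------

class Formula:
    """Base class; leaves are EPN-presence literals, internal nodes AND/OR/NOT."""

    def evaluate(self, present) -> bool:
        raise NotImplementedError


@dataclass(frozen=True)
class Lit(Formula):
    epn: str

    def evaluate(self, present):
        return self.epn in present

    def __str__(self):
        return self.epn


@dataclass(frozen=True)
class Not(Formula):
    child: Formula

    def evaluate(self, present):
        return not self.child.evaluate(present)

    def __str__(self):
        return f"!{_paren(self.child)}"


@dataclass(frozen=True)
class And(Formula):
    children: tuple

    def evaluate(self, present):
        return all(c.evaluate(present) for c in self.children)

    def __str__(self):
        return " & ".join(_paren(c) for c in self.children) if self.children else "1"


@dataclass(frozen=True)
class Or(Formula):
    children: tuple

    def evaluate(self, present):
        return any(c.evaluate(present) for c in self.children)

    def __str__(self):
        return " | ".join(_paren(c) for c in self.children) if self.children else "0"


class _Const(Formula):
    def __init__(self, value: bool):
        self.value = value

    def evaluate(self, present):
        return self.value

    def __str__(self):
        return "1" if self.value else "0"

    def __repr__(self):
        return f"<{self}>"


TRUE = _Const(True)
FALSE = _Const(False)


class NotTainted(Formula):
    """Sentinel for a subtree containing a NOT operator; the enclosing
    modulation arc is ignored."""

    def evaluate(self, present):
        raise ValueError("NOT-tainted formula has no truth value")

    def __str__(self):
        return "<not-tainted>"


NOT_TAINTED = NotTainted()


def _paren(f: Formula) -> str:
    s = str(f)
    return f"({s})" if isinstance(f, (And, Or)) and len(f.children) > 1 else s


def variables(f: Formula) -> set:
    if isinstance(f, Lit):
        return {f.epn}
    if isinstance(f, Not):
        return variables(f.child)
    if isinstance(f, (And, Or)):
        return set().union(*(variables(c) for c in f.children)) if f.children else set()
    return set()


# --------------------------------------------------------------------------
# logic(n) and mod(p)
# --------------------------------------------------------------------------

def logic_of(pdmap: PDMap, node: str) -> Formula:
    """Satisfaction formula of a modulation origin.

    EPN -> its presence literal; AND node -> conjunction of its inputs'
    formulas; OR node -> disjunction.  Any subtree that reaches a NOT
    operator taints the whole formula (NOT_TAINTED), which makes the
    enclosing modulation arc ignored.
    """
    if node in pdmap.epns:
        return Lit(node)
    op = pdmap.operators.get(node)
    if op is None:
        raise KeyError(f"unknown modulation origin {node!r}")
    if op.kind == "NOT":
        return NOT_TAINTED
    parts = [logic_of(pdmap, i) for i in sorted(op.inputs)]
    if any(isinstance(p, NotTainted) for p in parts):
        return NOT_TAINTED
    return And(tuple(parts)) if op.kind == "AND" else Or(tuple(parts))


def _usable_origin_formulas(pdmap: PDMap, origins, pid: str) -> list:
    out = []
    for n in origins:
        f = logic_of(pdmap, n)
        if isinstance(f, NotTainted):
            logger.warning("modulation origin %s of process %s routes through a "
                           "NOT operator: arc ignored", n, pid)
            continue
        out.append(f)
    return out


def mod_of(pdmap: PDMap, pid: str) -> Formula:
    """Permissive occurrence formula mod(p).

    With R = req(p), A = act(p), I = inh(p) (generic-modulation and
    NOT-tainted arcs removed first):

    * A = I = empty:  AND over R of logic(n)
    * otherwise:      AND over R  AND  (OR over A of logic(n)
                      OR  OR over I of NOT logic(n))

    Empty conjunction is TRUE, empty disjunction FALSE.
    """
    if pid not in pdmap.processes:
        raise KeyError(f"unknown process {pid!r}")
    R = _usable_origin_formulas(pdmap, pdmap.req(pid), pid)
    A = _usable_origin_formulas(pdmap, pdmap.act(pid), pid)
    I = _usable_origin_formulas(pdmap, pdmap.inh(pid), pid)
    req_part: Formula
    if not R:
        req_part = TRUE
    elif len(R) == 1:
        req_part = R[0]
    else:
        req_part = And(tuple(R))
    if not A and not I:
        return req_part
    disj_parts = tuple(A) + tuple(Not(f) for f in I)
    disj: Formula = disj_parts[0] if len(disj_parts) == 1 else Or(disj_parts)
    if req_part is TRUE:
        return disj
    return And((req_part, disj))


# --------------------------------------------------------------------------
# Disjunctive normal form
# --------------------------------------------------------------------------
# A clause is a frozenset of (epn, polarity) literals; a DNF is a frozenset
# of clauses.  TRUE -> {{}} (one empty clause); FALSE -> {} (no clause).

def _nnf(f: Formula, neg: bool = False) -> Formula:
    if isinstance(f, _Const):
        return FALSE if (f.value == neg) else TRUE
    if isinstance(f, Lit):
        return Not(f) if neg else f
    if isinstance(f, Not):
        return _nnf(f.child, not neg)
    if isinstance(f, And):
        kids = tuple(_nnf(c, neg) for c in f.children)
        return Or(kids) if neg else And(kids)
    if isinstance(f, Or):
        kids = tuple(_nnf(c, neg) for c in f.children)
        return And(kids) if neg else Or(kids)
    raise ValueError(f"cannot normalize {f!r}")


def _dnf_sets(f: Formula) -> frozenset:
    if isinstance(f, _Const):
        return frozenset({frozenset()}) if f.value else frozenset()
    if isinstance(f, Lit):
        return frozenset({frozenset({(f.epn, True)})})
    if isinstance(f, Not):     # NNF guarantees the child is a literal
        assert isinstance(f.child, Lit)
        return frozenset({frozenset({(f.child.epn, False)})})
    if isinstance(f, Or):
        return frozenset().union(*(_dnf_sets(c) for c in f.children))
    if isinstance(f, And):
        clause_sets = [_dnf_sets(c) for c in f.children]
        if not clause_sets:
            return frozenset({frozenset()})
        out = {frozenset()}
        for cs in clause_sets:
            nxt = set()
            for left, right in itertools.product(out, cs):
                merged = left | right
                if any((v, not pol) in merged for v, pol in merged):
                    continue   # contradictory clause dropped
                nxt.add(merged)
            out = nxt
        return frozenset(out)
    raise ValueError(f"cannot convert {f!r}")


def _prune_subsumed(clauses: frozenset) -> frozenset:
    kept = [c for c in clauses
            if not any(other < c for other in clauses)]
    return frozenset(kept)


def to_dnf(formula: Formula) -> frozenset:
    """Logically equivalent DNF with contradictory and subsumed clauses removed."""
    return _prune_subsumed(_dnf_sets(_nnf(formula)))


def dnf_sorted(clauses: frozenset) -> tuple:
    """Canonical ordering of a DNF for reproducible iteration/rendering."""
    return tuple(sorted((tuple(sorted(c)) for c in clauses)))


def render_dnf(clauses: frozenset) -> str:
    if not clauses:
        return "0"
    parts = []
    for clause in dnf_sorted(clauses):
        if not clause:
            return "1"
        parts.append(" & ".join(f"{'' if pol else '!'}{v}" for v, pol in clause))
    return " | ".join(parts)


# --------------------------------------------------------------------------
# cond(p): expansion into local-state conditions
# --------------------------------------------------------------------------

def local_states_of_literal(epn: str, polarity: bool, stories,
                            strict_formula: bool = False) -> tuple:
    """ls(x): local states matching a signed EPN-presence literal.

    For a non-story EPN the present/absent states of its own automaton.
    For an EPN of a story, presence is the story automaton sitting at that
    EPN's state; absence is any OTHER state of the story automaton,
    including the empty state (the entity may be absent altogether).  With
    ``strict_formula`` the empty state is excluded, reproducing the bare
    set-builder form of the absence case.
    """
    story = stories.story_of(epn) if stories is not None else None
    if story is None:
        return ((epn, "1"),) if polarity else ((epn, "0"),)
    sid = story.id
    if polarity:
        return ((sid, epn),)
    states = [(sid, f) for f in sorted(story.epns) if f != epn]
    if not strict_formula:
        states.append((sid, "empty"))
    return tuple(states)


def conditions_of(pdmap: PDMap, pid: str, stories=None,
                  strict_formula: bool = False) -> tuple:
    """cond(p): sets of local states (automaton, state) satisfying DNF(mod(p)).

    Union over DNF clauses of the cartesian product of ls() over the
    clause's literals.  Conditions requiring two local states of one
    automaton are unsatisfiable and dropped.  Result is deduplicated and
    canonically ordered; an empty tuple means the process can never occur.
    """
    from .stories import StorySet
    if stories is None:
        stories = StorySet(())
    clauses = to_dnf(mod_of(pdmap, pid))
    if not clauses:
        logger.warning("process %s has an unsatisfiable modulation formula and "
                       "can never occur", pid)
    conds = set()
    for clause in dnf_sorted(clauses):
        choices = [local_states_of_literal(v, pol, stories, strict_formula)
                   for v, pol in clause]
        for combo in itertools.product(*choices):
            automata = [a for a, _ in combo]
            if len(set(automata)) < len(automata):
                # two required states of a single automaton: unsatisfiable
                # unless they coincide
                cond = frozenset(combo)
                if len({a for a, _ in cond}) < len(cond):
                    continue
                conds.add(cond)
            else:
                conds.add(frozenset(combo))
    return tuple(sorted(conds, key=lambda c: tuple(sorted(c))))
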