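"""Worked-example builders and a seeded random-map generator.

The named fixtures are the small maps and the automata network used to
illustrate both semantics throughout the package: a three-automaton
example network, a phosphorylation/association map of seven EPNs, two
toy pathways exercising the story machinery, and a reduced rendition of
a receptor-mediated ERK activation topology (receptor vs β-arrestin
story alternatives).  ``random_map`` drives the oracle and property
suites with reproducible structurally valid maps.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from .encoding import AutomataNetwork, LocalTransition
from .map_model import (EntityPoolNode, LogicalOperatorNode, ModulationArc,
                        PDMap, ProcessNode, read_plain)

WORKED_EXAMPLE_PLAIN = """\
# one phosphorylation (p, stimulated by m) and one association (q)
epn a macromolecule label=a
epn aP macromolecule label=a state=phos:P
epn atp simple-chemical label=atp
epn adp simple-chemical label=adp
epn b macromolecule label=b
epn c complex label=c components=a;b
epn m macromolecule label=m
process p process
consume p a
consume p atp
produce p aP
produce p adp
modulate stimulation m p
process q association
consume q a
consume q b
produce q c
"""

WORKED_EXAMPLE_INITIAL = frozenset({"a", "atp", "b", "m"})

TOY_CHAIN_ASSOC_PLAIN = """\
# A -> B ; B + C -> D
epn A macromolecule label=A
epn B macromolecule label=B
epn C macromolecule label=C
epn D complex label=D components=B;C
process p1 process
consume p1 A
produce p1 B
process p2 association
consume p2 B
consume p2 C
produce p2 D
"""

TOY_TRANSFORM_ASSOC_PLAIN = """\
# A -> B ; A + B -> C
epn A macromolecule label=A
epn B macromolecule label=B
epn C complex label=C components=A;B
process p1 process
consume p1 A
produce p1 B
process p2 association
consume p2 A
consume p2 B
produce p2 C
"""

# Reduced receptor / G-protein / beta-arrestin topology: the receptor HR can
# be phosphorylated on two sites and captured by either beta-arrestin; the
# G-protein branch relays through PIP2/DAG and PKC to ERK, the arrestin
# branch reaches ERK directly.  Used for qualitative story-set regression
# (receptor-story vs beta-arrestin-stories alternatives).
AT1AR_SKELETON_PLAIN = """\
epn HR macromolecule label=HR
epn HRp1 macromolecule label=HR state=site1:P
epn HRp2 macromolecule label=HR state=site2:P
epn HRb1 complex label=HRb1 components=HR;barr1
epn HRb2 complex label=HRb2 components=HR;barr2
epn barr1 macromolecule label=barr1
epn barr2 macromolecule label=barr2
epn GRK23 macromolecule label=GRK23
epn GRK56 macromolecule label=GRK56
epn Gq macromolecule label=Gq
epn GqA macromolecule label=Gq state=act:on
epn PIP2 simple-chemical label=PIP2
epn DAG simple-chemical label=DAG
epn PKC macromolecule label=PKC
epn PKCa macromolecule label=PKC state=act:on
epn ERK macromolecule label=ERK
epn ERKp macromolecule label=ERK state=phos:P
process ph1 process
consume ph1 HR
produce ph1 HRp1
modulate catalysis GRK23 ph1
process ph2 process
consume ph2 HR
produce ph2 HRp2
modulate catalysis GRK56 ph2
process bind1 association
consume bind1 HRp2
consume bind1 barr1
produce bind1 HRb1
process bind2 association
consume bind2 HRp2
consume bind2 barr2
produce bind2 HRb2
process gact process
consume gact Gq
produce gact GqA
modulate stimulation HRp1 gact
process plc process
consume plc PIP2
produce plc DAG
modulate catalysis GqA plc
process pkcact process
consume pkcact PKC
produce pkcact PKCa
modulate stimulation DAG pkcact
process erk1 process
consume erk1 ERK
produce erk1 ERKp
modulate catalysis PKCa erk1
process erk2 process
consume erk2 ERK
produce erk2 ERKp
modulate catalysis HRb2 erk2
"""


def _three_automata_an() -> AutomataNetwork:
    T = [
        LocalTransition("a", "0", "1", {("b", "1")}),
        LocalTransition("a", "1", "2", {("c", "1")}),
        LocalTransition("b", "1", "0", {("a", "0"), ("c", "0")}),
        LocalTransition("c", "0", "1", {("a", "1")}),
    ]
    return AutomataNetwork({"a": ("0", "1", "2"), "b": ("0", "1"),
                            "c": ("0", "1")}, T)


_FIXTURES = {
    "three_automata_an": _three_automata_an,
    "worked_example": lambda: read_plain(WORKED_EXAMPLE_PLAIN),
    "toy_chain_assoc": lambda: read_plain(TOY_CHAIN_ASSOC_PLAIN),
    "toy_transform_assoc": lambda: read_plain(TOY_TRANSFORM_ASSOC_PLAIN),
    "at1ar_skeleton": lambda: read_plain(AT1AR_SKELETON_PLAIN),
}


def fixture(name: str):
    """Return a named fixture (a PDMap, or an AutomataNetwork for three_automata_an)."""
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(_FIXTURES)}")
    return builder()


# --------------------------------------------------------------------------
# Random maps
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MapRecipe:
    n_epns: int = 5
    n_processes: int = 3
    modulation_density: float = 0.5   # expected modulation arcs per process
    operator_prob: float = 0.0        # probability a modulation origin is an
    #                                   AND/OR over two EPNs
    source_prob: float = 0.15
    sink_prob: float = 0.15
    generic_prob: float = 0.1         # fraction of generic 'modulation' arcs
    seed: int = 0

    def __post_init__(self):
        if self.n_epns <= 0 or self.n_processes < 0:
            raise ValueError("recipe needs positive sizes")
        if self.modulation_density > 0 and self.n_epns == 0:
            raise ValueError("modulation density requires EPNs")


def random_map(recipe: MapRecipe) -> PDMap:
    """A seeded, structurally valid random map.

    Every process carries at least one flux arc or a source/sink flag;
    operator inputs are EPNs only (acyclic by construction); no NOT
    operators are ever generated.
    """
    rng = random.Random(recipe.seed)
    epn_ids = [f"e{i}" for i in range(recipe.n_epns)]
    epns = {e: EntityPoolNode(e, "macromolecule", label=e) for e in epn_ids}
    processes = {}
    operators = {}
    modulations = []
    for i in range(recipe.n_processes):
        pid = f"p{i}"
        reactants = frozenset(rng.sample(epn_ids, rng.randint(0, min(2, len(epn_ids)))))
        products = frozenset(rng.sample(epn_ids, rng.randint(0, min(2, len(epn_ids)))))
        if reactants:
            has_source = rng.random() < recipe.source_prob
        else:
            has_source = rng.random() < 0.9
        has_sink = rng.random() < recipe.sink_prob
        if not reactants and not products and not has_source:
            has_sink = True
        processes[pid] = ProcessNode(pid, "process", reactants, products,
                                     has_source_reactant=has_source,
                                     has_sink_product=has_sink)
        n_mods = 0
        while rng.random() < recipe.modulation_density and n_mods < 3:
            n_mods += 1
            if rng.random() < recipe.operator_prob and len(epn_ids) >= 2:
                oid = f"op{len(operators)}"
                kind = rng.choice(["AND", "OR"])
                inputs = frozenset(rng.sample(epn_ids, 2))
                operators[oid] = LogicalOperatorNode(oid, kind, inputs)
                origin = oid
            else:
                origin = rng.choice(epn_ids)
            if rng.random() < recipe.generic_prob:
                cls = "modulation"
            else:
                cls = rng.choice(["stimulation", "catalysis", "inhibition",
                                  "necessary-stimulation"])
            modulations.append(ModulationArc(origin, pid, cls))
    return PDMap(epns=epns, processes=processes, operators=operators,
                 modulations=tuple(modulations))
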