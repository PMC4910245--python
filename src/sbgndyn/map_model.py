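"""SBGN-PD map model: entity pools, processes, modulations, logical operators.

The map is the static input to both qualitative semantics.  Entity pool
nodes (EPNs) represent pools of molecular entities; process nodes consume
and produce EPNs through flux arcs; modulation arcs (stimulation,
catalysis, inhibition, necessary stimulation, or the generic modulation)
describe the effect an EPN — or a logical combination of EPNs — has on a
process.  Source and sink glyphs stand for unspecified origins and
destinations of synthesis/degradation; they are role-tagged on the
process and excluded from ``in(p)``/``out(p)``.

Two serializations are supported: SBGN-ML (the XML exchange format for
SBGN maps, PD language) and a line-oriented plain format used for
fixtures and tests.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

from lxml import etree

logger = logging.getLogger(__name__)

EPN_CLASSES = frozenset({
    "unspecified-entity", "simple-chemical", "macromolecule",
    "nucleic-acid-feature", "complex", "perturbing-agent", "source-sink",
})
PROCESS_CLASSES = frozenset({
    "process", "omitted-process", "uncertain-process",
    "association", "dissociation", "phenotype",
})
MODULATION_CLASSES = frozenset({
    "modulation", "stimulation", "catalysis", "inhibition",
    "necessary-stimulation",
})
OPERATOR_KINDS = frozenset({"AND", "OR", "NOT"})


class MapError(Exception):
    """Base class for map construction and parsing errors."""


class SbgnParseError(MapError):
    """Malformed XML or structurally unusable SBGN-ML document."""


class UnsupportedLanguageError(MapError):
    """The document's map is not in the process description language."""


class IntegrityError(MapError):
    """An arc or operator references an id that does not exist."""


@dataclass(frozen=True)
class EntityPoolNode:
    id: str
    epn_class: str
    label: str = ""
    compartment: Optional[str] = None
    state_decorations: frozenset = frozenset()   # of (variable, value) pairs
    component_labels: frozenset = frozenset()    # labels of complex members
    is_clone: bool = False

    def __post_init__(self):
        if self.epn_class not in EPN_CLASSES:
            raise MapError(f"unknown EPN class {self.epn_class!r} for {self.id!r}")
        if self.epn_class == "source-sink" and self.state_decorations:
            raise MapError(f"source/sink {self.id!r} cannot carry state decorations")

    @property
    def identity(self) -> tuple:
        """Clone-merging identity: two EPNs with equal identity are one pool."""
        return (self.epn_class, self.label, self.compartment,
                tuple(sorted(self.state_decorations)),
                tuple(sorted(self.component_labels)))

    @property
    def is_source_sink(self) -> bool:
        return self.epn_class == "source-sink"


@dataclass(frozen=True)
class ProcessNode:
    id: str
    process_class: str
    reactants: frozenset = frozenset()   # EPN ids, sources excluded
    products: frozenset = frozenset()    # EPN ids, sinks excluded
    has_source_reactant: bool = False
    has_sink_product: bool = False

    def __post_init__(self):
        if self.process_class not in PROCESS_CLASSES:
            raise MapError(f"unknown process class {self.process_class!r} for {self.id!r}")


@dataclass(frozen=True)
class ModulationArc:
    origin: str      # EPN id or logical-operator id
    target: str      # process id
    mod_class: str

    def __post_init__(self):
        if self.mod_class not in MODULATION_CLASSES:
            raise MapError(f"unknown modulation class {self.mod_class!r}")


@dataclass(frozen=True)
class LogicalOperatorNode:
    id: str
    kind: str                      # AND / OR / NOT
    inputs: frozenset = frozenset()  # EPN or operator ids

    def __post_init__(self):
        if self.kind not in OPERATOR_KINDS:
            raise MapError(f"unknown operator kind {self.kind!r} for {self.id!r}")
        if not self.inputs:
            raise MapError(f"operator {self.id!r} has no inputs")


@dataclass(frozen=True)
class PDMap:
    """An SBGN-PD map after clone merging.

    ``epns``/``processes``/``operators`` are id-keyed mappings; iteration is
    always in lexicographic id order for reproducibility.
    """

    epns: Mapping[str, EntityPoolNode] = field(default_factory=dict)
    processes: Mapping[str, ProcessNode] = field(default_factory=dict)
    operators: Mapping[str, LogicalOperatorNode] = field(default_factory=dict)
    modulations: tuple = ()
    compartments: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "epns", dict(sorted(self.epns.items())))
        object.__setattr__(self, "processes", dict(sorted(self.processes.items())))
        object.__setattr__(self, "operators", dict(sorted(self.operators.items())))
        object.__setattr__(self, "modulations", tuple(sorted(
            set(self.modulations), key=lambda m: (m.target, m.mod_class, m.origin))))
        self._check_integrity()

    def _check_integrity(self) -> None:
        for pid, p in self.processes.items():
            for eid in sorted(p.reactants | p.products):
                e = self.epns.get(eid)
                if e is None:
                    raise IntegrityError(f"process {pid!r} references unknown EPN {eid!r}")
                if e.is_source_sink:
                    raise IntegrityError(
                        f"process {pid!r} lists source/sink {eid!r} as reactant/product; "
                        "use the has_source_reactant/has_sink_product flags")
        for m in self.modulations:
            if m.origin not in self.epns and m.origin not in self.operators:
                raise IntegrityError(f"modulation arc references unknown origin {m.origin!r}")
            if m.target not in self.processes:
                raise IntegrityError(f"modulation arc targets unknown process {m.target!r}")
        for op in self.operators.values():
            for i in sorted(op.inputs):
                if i not in self.epns and i not in self.operators:
                    raise IntegrityError(f"operator {op.id!r} references unknown input {i!r}")

    # --- accessors used throughout the semantics -------------------------

    def pool_epns(self) -> list:
        """Non-source/sink EPN ids, sorted."""
        return sorted(e for e, n in self.epns.items() if not n.is_source_sink)

    def in_(self, pid: str) -> frozenset:
        """in(p): reactant EPNs of p, sources excluded."""
        return self.processes[pid].reactants

    def out(self, pid: str) -> frozenset:
        """out(p): product EPNs of p, sinks excluded."""
        return self.processes[pid].products

    def _mod_origins(self, pid: str, classes) -> tuple:
        return tuple(sorted(m.origin for m in self.modulations
                            if m.target == pid and m.mod_class in classes))

    def req(self, pid: str) -> tuple:
        """Origins of necessary-stimulation arcs on p."""
        return self._mod_origins(pid, {"necessary-stimulation"})

    def act(self, pid: str) -> tuple:
        """Origins of stimulation and catalysis arcs on p."""
        return self._mod_origins(pid, {"stimulation", "catalysis"})

    def inh(self, pid: str) -> tuple:
        """Origins of inhibition arcs on p."""
        return self._mod_origins(pid, {"inhibition"})


# --------------------------------------------------------------------------
# Clone merging
# --------------------------------------------------------------------------

def merge_clones(pdmap: PDMap) -> PDMap:
    """Merge EPNs that denote the same pool (identical identity tuple).

    Clone markers duplicate an EPN for layout; all duplicates refer to one
    pool, so arcs are remapped onto a single representative (the
    lexicographically smallest id).  Source/sink glyphs are never merged,
    and neither are anonymous EPNs (no label, decorations or components,
    and no clone marker): they carry no evidence of denoting one pool.
    Idempotent.
    """
    groups: dict = {}
    for eid, e in pdmap.epns.items():
        if e.is_source_sink:
            continue
        if not (e.is_clone or e.label or e.state_decorations or e.component_labels):
            continue
        groups.setdefault(e.identity, []).append(eid)
    remap = {}
    for ids in groups.values():
        rep = min(ids)
        for eid in ids:
            remap[eid] = rep
    epns = {}
    for eid, e in pdmap.epns.items():
        tgt = remap.get(eid, eid)
        if tgt == eid:
            epns[eid] = replace(e, is_clone=False) if e.is_clone else e
    processes = {
        pid: replace(p,
                     reactants=frozenset(remap.get(e, e) for e in p.reactants),
                     products=frozenset(remap.get(e, e) for e in p.products))
        for pid, p in pdmap.processes.items()}
    operators = {
        oid: replace(op, inputs=frozenset(remap.get(i, i) for i in op.inputs))
        for oid, op in pdmap.operators.items()}
    modulations = tuple(replace(m, origin=remap.get(m.origin, m.origin))
                        for m in pdmap.modulations)
    return PDMap(epns=epns, processes=processes, operators=operators,
                 modulations=modulations, compartments=pdmap.compartments)


# --------------------------------------------------------------------------
# Validation report
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Finding:
    severity: str   # "error" | "warning"
    code: str
    message: str
    subject: str = ""


def _operator_closure(pdmap: PDMap, origin: str) -> set:
    """All operator ids reachable upward from a modulation origin."""
    seen, stack = set(), [origin]
    while stack:
        n = stack.pop()
        op = pdmap.operators.get(n)
        if op is None or n in seen:
            continue
        seen.add(n)
        stack.extend(op.inputs)
    return seen


def _operator_cycles(pdmap: PDMap) -> list:
    import networkx as nx
    g = nx.DiGraph()
    for oid, op in pdmap.operators.items():
        for i in op.inputs:
            if i in pdmap.operators:
                g.add_edge(i, oid)
        g.add_node(oid)
    return [sorted(c) for c in nx.simple_cycles(g)]


def validate_map(pdmap: PDMap) -> list:
    """Report-only structural checks; returns a list of findings.

    Warnings flag constructs the semantics silently drops (NOT operators,
    generic modulation arcs); errors flag structures that make downstream
    formulas undefined (operator cycles).
    """
    findings = []
    for cyc in _operator_cycles(pdmap):
        findings.append(Finding("error", "operator-cycle",
                                f"logical operator cycle: {' -> '.join(cyc)}",
                                subject=cyc[0]))
    for m in pdmap.modulations:
        if m.mod_class == "modulation":
            findings.append(Finding(
                "warning", "generic-modulation-ignored",
                f"generic modulation arc {m.origin} -> {m.target} has unknown "
                "effect and is ignored by the semantics", subject=m.target))
        closure = _operator_closure(pdmap, m.origin)
        if any(pdmap.operators[o].kind == "NOT" for o in closure):
            findings.append(Finding(
                "warning", "not-operator-ignored",
                f"modulation arc {m.origin} -> {m.target} routes through a NOT "
                "operator, which has no dynamical meaning; the arc is ignored",
                subject=m.target))
    for pid, p in sorted(pdmap.processes.items()):
        if (not p.reactants and not p.products
                and not p.has_source_reactant and not p.has_sink_product):
            findings.append(Finding("warning", "isolated-process",
                                    f"process {pid} has no flux arcs", subject=pid))
    return findings


# --------------------------------------------------------------------------
# SBGN-ML (XML) reading and writing
# --------------------------------------------------------------------------

_EPN_XML_CLASSES = {
    "unspecified entity": "unspecified-entity",
    "simple chemical": "simple-chemical",
    "macromolecule": "macromolecule",
    "nucleic acid feature": "nucleic-acid-feature",
    "complex": "complex",
    "perturbing agent": "perturbing-agent",
    "source and sink": "source-sink",
    "empty set": "source-sink",   # SBGN-ML 0.3 renaming
}
_PROCESS_XML_CLASSES = {
    "process": "process", "omitted process": "omitted-process",
    "uncertain process": "uncertain-process", "association": "association",
    "dissociation": "dissociation", "phenotype": "phenotype",
}
_MOD_XML_CLASSES = {
    "modulation": "modulation", "stimulation": "stimulation",
    "catalysis": "catalysis", "inhibition": "inhibition",
    "necessary stimulation": "necessary-stimulation",
}
_IGNORED_GLYPHS = {"unit of information", "submap", "tag", "annotation",
                   "terminal", "cardinality", "stoichiometry"}


def _local(el) -> str:
    return etree.QName(el).localname


def _children(el, name):
    return [c for c in el if isinstance(c.tag, str) and _local(c) == name]


def read_sbgnml(source, merge: bool = True) -> PDMap:
    """Parse an SBGN-ML (0.2 or 0.3) process description document.

    ``source`` may be a path, a file-like object, or an XML string/bytes.
    Clones are merged unless ``merge`` is false.  Unknown glyph classes are
    skipped with a warning; equivalence arcs and submaps are dropped.
    """
    try:
        if isinstance(source, str) and source.lstrip().startswith("<"):
            root = etree.fromstring(source.encode())
        elif isinstance(source, bytes):
            root = etree.fromstring(source)
        else:
            root = etree.parse(source).getroot()
    except (etree.XMLSyntaxError, OSError) as exc:
        raise SbgnParseError(f"cannot parse SBGN-ML document: {exc}") from exc

    maps = [el for el in root.iter() if isinstance(el.tag, str) and _local(el) == "map"]
    if not maps:
        raise SbgnParseError("document contains no <map> element")
    map_el = maps[0]
    language = map_el.get("language", "")
    if language and "process description" not in language.lower():
        raise UnsupportedLanguageError(
            f"map language {language!r} is not process description")

    epns, processes, operators, compartments = {}, {}, {}, {}
    port_owner, flags = {}, {}
    proc_reactants: dict = {}
    proc_products: dict = {}

    def register_ports(glyph, owner_id):
        for port in _children(glyph, "port"):
            pid = port.get("id")
            if pid:
                port_owner[pid] = owner_id

    def glyph_label(glyph) -> str:
        for lab in _children(glyph, "label"):
            return lab.get("text", "") or ""
        return ""

    def parse_epn(glyph, cls):
        gid = glyph.get("id")
        decorations, components = set(), set()
        is_clone = bool(_children(glyph, "clone"))
        for sub in _children(glyph, "glyph"):
            sub_cls = sub.get("class", "")
            if sub_cls == "state variable":
                for st in _children(sub, "state"):
                    decorations.add((st.get("variable", "") or "",
                                     st.get("value", "") or ""))
            elif sub_cls in _EPN_XML_CLASSES:   # complex member
                components.add(glyph_label(sub))
            elif sub_cls == "unit of information":
                pass  # parsed but semantically ignored
        epns[gid] = EntityPoolNode(
            id=gid, epn_class=cls, label=glyph_label(glyph),
            compartment=glyph.get("compartmentRef"),
            state_decorations=frozenset(decorations),
            component_labels=frozenset(components), is_clone=is_clone)
        register_ports(glyph, gid)

    for glyph in _children(map_el, "glyph"):
        cls = glyph.get("class", "")
        gid = glyph.get("id")
        if cls in _EPN_XML_CLASSES:
            parse_epn(glyph, _EPN_XML_CLASSES[cls])
        elif cls in _PROCESS_XML_CLASSES:
            processes[gid] = _PROCESS_XML_CLASSES[cls]
            proc_reactants[gid] = set()
            proc_products[gid] = set()
            flags[gid] = [False, False]
            register_ports(glyph, gid)
        elif cls in ("and", "or", "not"):
            operators[gid] = [cls.upper(), set()]
            register_ports(glyph, gid)
        elif cls == "compartment":
            compartments[gid] = glyph_label(glyph)
        else:
            if cls not in _IGNORED_GLYPHS:
                logger.warning("unknown glyph class %r (id=%s): skipped", cls, gid)
            else:
                logger.warning("glyph %s of class %r not interpreted", gid, cls)

    def resolve(ref, arc_id):
        node = port_owner.get(ref, ref)
        if node not in epns and node not in processes and node not in operators:
            raise IntegrityError(f"arc {arc_id!r} references unknown node {ref!r}")
        return node

    modulations = []
    for arc in _children(map_el, "arc"):
        cls = arc.get("class", "")
        aid = arc.get("id", "?")
        src = resolve(arc.get("source"), aid)
        tgt = resolve(arc.get("target"), aid)
        if cls == "consumption":
            if tgt not in processes:
                raise IntegrityError(f"consumption arc {aid!r} must target a process")
            if epns.get(src) is not None and epns[src].is_source_sink:
                flags[tgt][0] = True
            elif src in epns:
                proc_reactants[tgt].add(src)
            else:
                raise IntegrityError(f"consumption arc {aid!r} source is not an EPN")
        elif cls == "production":
            if src not in processes:
                raise IntegrityError(f"production arc {aid!r} must leave a process")
            if epns.get(tgt) is not None and epns[tgt].is_source_sink:
                flags[src][1] = True
            elif tgt in epns:
                proc_products[src].add(tgt)
            else:
                raise IntegrityError(f"production arc {aid!r} target is not an EPN")
        elif cls in _MOD_XML_CLASSES:
            if tgt not in processes:
                raise IntegrityError(f"modulation arc {aid!r} must target a process")
            modulations.append(ModulationArc(src, tgt, _MOD_XML_CLASSES[cls]))
        elif cls == "logic arc":
            if tgt not in operators:
                raise IntegrityError(f"logic arc {aid!r} must target an operator")
            operators[tgt][1].add(src)
        elif cls == "equivalence arc":
            logger.warning("equivalence arc %s dropped", aid)
        else:
            logger.warning("unknown arc class %r (id=%s): skipped", cls, aid)

    # source/sink glyphs with no remaining role are kept in the map so that
    # validation can see them, but they never enter in(p)/out(p).
    pdmap = PDMap(
        epns=epns,
        processes={pid: ProcessNode(pid, cls,
                                    frozenset(proc_reactants[pid]),
                                    frozenset(proc_products[pid]),
                                    has_source_reactant=flags[pid][0],
                                    has_sink_product=flags[pid][1])
                   for pid, cls in processes.items()},
        operators={oid: LogicalOperatorNode(oid, kind, frozenset(inputs))
                   for oid, (kind, inputs) in operators.items() if inputs},
        modulations=tuple(modulations),
        compartments=compartments)
    return merge_clones(pdmap) if merge else pdmap


_SBGN_NS = "http://sbgn.org/libsbgn/0.2"


def write_sbgnml(pdmap: PDMap) -> str:
    """Serialize a map to SBGN-ML 0.2 (layout-free: glyphs get zero bboxes)."""
    inv_epn = {v: k for k, v in _EPN_XML_CLASSES.items() if k != "empty set"}
    inv_proc = {v: k for k, v in _PROCESS_XML_CLASSES.items()}
    inv_mod = {v: k for k, v in _MOD_XML_CLASSES.items()}
    E = lambda tag, **attrs: etree.SubElement(parent_stack[-1], f"{{{_SBGN_NS}}}{tag}",
                                              **{k: v for k, v in attrs.items() if v is not None})
    root = etree.Element(f"{{{_SBGN_NS}}}sbgn")
    parent_stack = [root]
    map_el = E("map", language="process description")
    parent_stack.append(map_el)
    for cid, label in sorted(pdmap.compartments.items()):
        g = E("glyph", id=cid, **{"class": "compartment"})
        parent_stack.append(g)
        E("label", text=label)
        E("bbox", x="0", y="0", w="0", h="0")
        parent_stack.pop()
    for eid, e in pdmap.epns.items():
        g = E("glyph", id=eid, compartmentRef=e.compartment,
              **{"class": inv_epn[e.epn_class]})
        parent_stack.append(g)
        if e.label:
            E("label", text=e.label)
        E("bbox", x="0", y="0", w="0", h="0")
        for i, (var, val) in enumerate(sorted(e.state_decorations)):
            sv = E("glyph", id=f"{eid}__sv{i}", **{"class": "state variable"})
            parent_stack.append(sv)
            E("state", variable=var, value=val)
            E("bbox", x="0", y="0", w="0", h="0")
            parent_stack.pop()
        for i, lab in enumerate(sorted(e.component_labels)):
            sub = E("glyph", id=f"{eid}__c{i}", **{"class": "macromolecule"})
            parent_stack.append(sub)
            E("label", text=lab)
            E("bbox", x="0", y="0", w="0", h="0")
            parent_stack.pop()
        parent_stack.pop()
    for pid, p in pdmap.processes.items():
        g = E("glyph", id=pid, **{"class": inv_proc[p.process_class]})
        parent_stack.append(g)
        E("bbox", x="0", y="0", w="0", h="0")
        parent_stack.pop()
    for oid, op in pdmap.operators.items():
        g = E("glyph", id=oid, **{"class": op.kind.lower()})
        parent_stack.append(g)
        E("bbox", x="0", y="0", w="0", h="0")
        parent_stack.pop()

    counter = [0]
    aux = [0]

    def arc(cls, src, tgt):
        counter[0] += 1
        E("arc", id=f"arc{counter[0]}", source=src, target=tgt, **{"class": cls})

    for pid, p in pdmap.processes.items():
        for eid in sorted(p.reactants):
            arc("consumption", eid, pid)
        for eid in sorted(p.products):
            arc("production", pid, eid)
        if p.has_source_reactant:
            aux[0] += 1
            sid = f"__source{aux[0]}"
            g = E("glyph", id=sid, **{"class": "source and sink"})
            parent_stack.append(g)
            E("bbox", x="0", y="0", w="0", h="0")
            parent_stack.pop()
            arc("consumption", sid, pid)
        if p.has_sink_product:
            aux[0] += 1
            sid = f"__sink{aux[0]}"
            g = E("glyph", id=sid, **{"class": "source and sink"})
            parent_stack.append(g)
            E("bbox", x="0", y="0", w="0", h="0")
            parent_stack.pop()
            arc("production", pid, sid)
    for oid, op in pdmap.operators.items():
        for i in sorted(op.inputs):
            arc("logic arc", i, oid)
    for m in pdmap.modulations:
        arc({v: k for k, v in _MOD_XML_CLASSES.items()}[m.mod_class], m.origin, m.target)
    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode()


# --------------------------------------------------------------------------
# Internal plain map format
# --------------------------------------------------------------------------

def read_plain(text: str, merge: bool = True) -> PDMap:
    """Parse the line-oriented fixture format.

    Records::

        epn <id> <class> [label=..] [compartment=..] [state=var:val;..]
            [components=a;b] [clone]
        process <id> <class>
        consume <process> <epn>|SOURCE
        produce <process> <epn>|SINK
        modulate <class> <origin> <process>
        operator <id> AND|OR|NOT <input>+

    Lines starting with ``#`` and blank lines are skipped.
    """
    epns: dict = {}
    proc_class: dict = {}
    reac: dict = {}
    prod: dict = {}
    flags: dict = {}
    operators: dict = {}
    modulations = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        kind, args = tokens[0], tokens[1:]
        try:
            if kind == "epn":
                eid, cls, *opts = args
                kw = dict(label="", compartment=None)
                decorations, components, clone = set(), set(), False
                for o in opts:
                    if o == "clone":
                        clone = True
                    elif o.startswith("label="):
                        kw["label"] = o[6:]
                    elif o.startswith("compartment="):
                        kw["compartment"] = o[12:]
                    elif o.startswith("state="):
                        for pair in o[6:].split(";"):
                            var, _, val = pair.partition(":")
                            decorations.add((var, val))
                    elif o.startswith("components="):
                        components.update(o[11:].split(";"))
                    else:
                        raise MapError(f"unknown epn option {o!r}")
                epns[eid] = EntityPoolNode(
                    eid, cls, kw["label"], kw["compartment"],
                    frozenset(decorations), frozenset(components), clone)
            elif kind == "process":
                pid, cls = args
                proc_class[pid] = cls
                reac.setdefault(pid, set())
                prod.setdefault(pid, set())
                flags.setdefault(pid, [False, False])
            elif kind == "consume":
                pid, eid = args
                if eid == "SOURCE":
                    flags[pid][0] = True
                else:
                    reac[pid].add(eid)
            elif kind == "produce":
                pid, eid = args
                if eid == "SINK":
                    flags[pid][1] = True
                else:
                    prod[pid].add(eid)
            elif kind == "modulate":
                cls, origin, pid = args
                modulations.append(ModulationArc(origin, pid, cls))
            elif kind == "operator":
                oid, op_kind, *inputs = args
                operators[oid] = LogicalOperatorNode(oid, op_kind, frozenset(inputs))
            else:
                raise MapError(f"unknown record type {kind!r}")
        except (ValueError, KeyError) as exc:
            raise MapError(f"line {lineno}: cannot parse {line!r}: {exc}") from exc
    pdmap = PDMap(
        epns=epns,
        processes={pid: ProcessNode(pid, cls, frozenset(reac[pid]),
                                    frozenset(prod[pid]),
                                    has_source_reactant=flags[pid][0],
                                    has_sink_product=flags[pid][1])
                   for pid, cls in proc_class.items()},
        operators=operators, modulations=tuple(modulations))
    return merge_clones(pdmap) if merge else pdmap


def write_plain(pdmap: PDMap) -> str:
    lines = []
    for eid, e in pdmap.epns.items():
        parts = ["epn", eid, e.epn_class]
        if e.label:
            parts.append(f"label={e.label}")
        if e.compartment:
            parts.append(f"compartment={e.compartment}")
        if e.state_decorations:
            parts.append("state=" + ";".join(
                f"{v}:{w}" for v, w in sorted(e.state_decorations)))
        if e.component_labels:
            parts.append("components=" + ";".join(sorted(e.component_labels)))
        if e.is_clone:
            parts.append("clone")
        lines.append(" ".join(parts))
    for pid, p in pdmap.processes.items():
        lines.append(f"process {pid} {p.process_class}")
        for eid in sorted(p.reactants):
            lines.append(f"consume {pid} {eid}")
        if p.has_source_reactant:
            lines.append(f"consume {pid} SOURCE")
        for eid in sorted(p.products):
            lines.append(f"produce {pid} {eid}")
        if p.has_sink_product:
            lines.append(f"produce {pid} SINK")
    for oid, op in pdmap.operators.items():
        lines.append(f"operator {oid} {op.kind} " + " ".join(sorted(op.inputs)))
    for m in pdmap.modulations:
        lines.append(f"modulate {m.mod_class} {m.origin} {m.target}")
    return "\n".join(lines) + "\n"
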