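# sbgndyn

Qualitative dynamics for SBGN Process Description (SBGN-PD) reaction
networks, via asynchronous automata networks.

SBGN-PD is the standard graphical notation for reaction networks: entity
pool nodes (EPNs) for pools of molecular entities, process nodes for
reactions with flux arcs for consumption/production, and modulation arcs
(stimulation, catalysis, inhibition, necessary stimulation) for the
effects entities have on processes.  A map is static; to check it
against known behaviour — can the phosphorylated form ever appear? which
states are the attractors? can two cell-cycle phases coincide? — one
needs a dynamical semantics.  This package implements two:

* **General semantics.**  Every EPN is a Boolean automaton
  (absent/present) and every process a Boolean automaton
  (non-occurring/occurring).  A process starts occurring when all its
  (non-source) reactants are present, all necessary stimulations hold,
  and — if it is modulated at all — at least one stimulation holds or at
  least one inhibition fails (a deliberately permissive reading that
  over-approximates any sharper, unknown modulation logic).  It stops
  occurring when all its (non-sink) products are present; reactant
  consumption is optional, so partial consumption is explored too.
* **Stories semantics.**  A *story* is a set of EPNs representing the
  mutually exclusive physical states of one molecular entity
  (unphosphorylated / phosphorylated / in complex, ...), subject to four
  structural constraints (flux-path connectivity inside the story; a
  produced story EPN requires a story reactant; no process consumes, or
  produces, two story EPNs).  Each story becomes a single automaton with
  one state per member plus an *empty* state, so its EPNs can never be
  present simultaneously; processes acting on a common story are put in
  conflict (`p # q`) and cannot occur at once.  The result is a
  lower-dimensional sub-dynamics of the general semantics.

Formally, an automata network is a triple (Σ, S, T): automata names, per
automaton a finite set of local states, and local transitions
`a_i --l--> a_j` guarded by local states `l` of other automata.  Updates
are asynchronous: one applicable transition fires at a time.  Exhaustive
exploration from an initial state yields the state transition graph
(STG); attractors are its terminal strongly connected components (fixed
points when singletons).  Networks export to 1-bounded Petri nets (PNML)
for external model checkers, and to JSON/DOT.

## Worked example

The bundled `worked_example` map has seven EPNs: protein `a` is
phosphorylated into `aP` by process `p` (consuming `atp`, producing
`adp`, stimulated by `m`), and associates with `b` into complex `c` via
process `q`.

```python
>>> import sbgndyn as sd
>>> m = sd.fixture("worked_example")
>>> an = sd.encode(m)                       # general semantics
>>> an.summary()
'9 automata, 18 local states, 11 local transitions'
>>> init = sd.initial_global_state(an, m, {"a", "atp", "b", "m"})
>>> stg = sd.build_stg(an, init)
>>> stg.number_of_nodes()
88
>>> atts = sd.attractors(stg)
>>> len(atts), {a.kind for a in atts}
(9, {'point'})
>>> sum(1 for a in atts for s in a.states if s["aP"] == s["c"] == "1")
5
```

88 reachable states and nine fixed points: in five of them both `aP`
and `c` are present (each process fired while consuming `a` only
partially), in the other four the first process to fire consumed `a`
completely and blocked the second.  Under the stories semantics with
stories 𝔰 = {a, aP, c} and 𝔱 = {adp, atp}:

```python
>>> ss = sd.StorySet([sd.Story({"a", "aP", "c"}, name="s"),
...                   sd.Story({"adp", "atp"}, name="t")])
>>> an2 = sd.encode(m, ss)
>>> init2 = sd.initial_global_state(an2, m, {"a", "atp", "b", "m"}, ss)
>>> stg2 = sd.build_stg(an2, init2)
>>> stg2.number_of_nodes(), len(sd.attractors(stg2))
(11, 3)
```

The dynamics collapses to 11 states and three fixed points — two with
the story at the complex state `c` (differing in whether `b` was fully
consumed) and one at the phosphorylated state `aP`; `aP` and `c` can
never be present together, by construction.

The same pipeline is available from the shell:

```sh
sbgndyn validate map.sbgn
sbgndyn stories map.sbgn --epn-maximal
sbgndyn stg map.sbgn --init a,atp,b,m
sbgndyn reach map.sbgn --init a,atp,b,m --goal aP=1 --goal c=1
sbgndyn encode map.sbgn --pnml out.pnml
```

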