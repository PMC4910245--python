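# Methods

## Scope and model

`sbgndyn` turns an SBGN-PD map into an asynchronous automata network
under one of two qualitative semantics and analyzes the resulting
dynamics exhaustively.  Both semantics share one encoding; the general
semantics is the special case of an empty story set.  The package
assumes:

* **Boolean abstraction.**  An entity pool is absent or present; a
  process is non-occurring or occurring.  No stoichiometry, no kinetics,
  no population counts.  The abstraction over-approximates: behaviour
  absent here is absent in any quantitative refinement, while behaviour
  present here may be spurious.
* **Asynchrony.**  Exactly one local transition fires per step,
  non-deterministically.  Reactant consumption is decoupled from product
  production (a consumption transition may or may not fire before the
  process de-activates), which is what makes partial consumption
  explorable.
* **Permissive modulation.**  When several modulations target one
  process their joint logic is unknown, so the weakest meaningful rule
  is used: all necessary stimulations must hold, and at least one
  stimulation holds or one inhibition fails.  Generic `modulation` arcs
  (unknown effect) and arcs whose origin routes through a NOT operator
  (no dynamical meaning) are dropped, with a warning.

## From map to network

For each process `p`, the modulation formula `mod(p)` is built from the
origin formulas `logic(n)` (EPN literal; AND/OR over operator inputs),
converted to disjunctive normal form, and expanded into `cond(p)`: the
sets of local states that satisfy it.  For a story EPN `e` of story 𝔖,
presence means "the story automaton sits at `e`" and absence means "it
sits at any *other* state, **including the empty state**".  Including
the empty state is a deliberate reading of absence-as-such (the entity
may be gone altogether, not merely in another physical state); a
`strict_formula` flag excludes it for comparison.  DNF conversion is
negation-normal-form plus distribution with contradiction and
subsumption pruning — exact at desk scale, no minimization; a property
test cross-checks equivalence against sympy's independent converter.

Transitions follow the general-case scheme (activation on
`cond ∪ ready(p)`, production, consumption guarded by `done(p)`, story
moves, de-activation on `done(p)`), except in three shortcut cases
where a conflict-free process needs no automaton of its own: no
reactant pool; a single reactant and no product; a single reactant and
single product inside one story.  Shortcuts are on by default and can
be disabled (`shortcuts=False`), which keeps the state space's
dimension aligned with the rule-based interpreter used as an oracle.
Two printed-scheme corner cases are kept as specified rather than
"fixed": a reactant-less process with several products emits one
independent transition per product (products are not synchronized), and
a fully degenerate process (source-to-sink) gets an unconditioned
de-activation.  Conditions are canonical sorted tuples; a condition
requiring two states of one automaton is unsatisfiable and dropped at
encoding time, and a condition mentioning the transition's own origin
state is simplified (the reference is implied).

Story identifiers default to digests of their sorted EPN ids, so
encodings are reproducible without user-chosen names.

## Stories

Story enumeration explores connected subsets of the "share a process"
graph over non-source/sink EPNs (constraint (i) holds by construction),
prunes on the monotone constraints (iii)/(iv) during growth, and
filters on (ii), the optional shared-label constraint (v), and the size
bounds at the end.  Singleton stories are excluded by default
(`min_size=2`): a singleton's automaton is dynamics-equivalent to the
EPN's Boolean automaton.  Sources and sinks are excluded from stories
outright.  A story holding both a reactant and the sole stimulator of a
process would silence that process forever; this is detected and
reported as a note, not enforced as a constraint.

Valid (pairwise-disjoint) collections are the independent sets of the
story-intersection graph.  Inclusion-maximal ones are enumerated as
maximal cliques of the complement graph; *final* sets are obtained by a
posteriori dominance filtering among them (a dominating valid set
always extends to a dominating maximal one, so filtering among maximal
sets is exact); *epn-maximal* sets are the argmax of total EPN count
over the maximal sets — exact with all ties, since extending a valid
set never loses EPNs.  Seed stories are fixed into every candidate
before optimization.  The expected implication chain (epn-maximal ⇒
final ⇒ maximally valid) is asserted on all fixtures.

## Dynamics

STG construction is breadth-first with hash-consed global states; the
exploration order is irrelevant to the result and can be randomized
under a seed, which a property test exercises.  The default state cap
is 1,000,000 with a loud, resumable error — genome-scale maps are the
domain of unfolding-based model checkers, reachable through the PNML
export, not of explicit exploration.  Attractors are the terminal SCCs
of the STG (Tarjan-based condensation; linear in graph size).
Reachability goals are partial states (conjunctions of local states);
phase queries are disjunctions over markers, where a story member's
presence is its story-automaton state.  Disabling a marker removes all
transitions through its present state; for a story member this also
blocks traversal of the story through that state — a stronger cut than
in the Boolean case, stated here because the two are easily conflated.

`oracle_successors` interprets the four general-semantics rules
directly on the map, sharing nothing with the encoding path; agreement
of the two routes on every reachable state of 1000 seeded random maps
is part of the test suite.

## Parsing and identity

SBGN-ML 0.2/0.3 PD documents are parsed with lxml; ports are resolved
to their glyphs, source-and-sink glyphs become role flags on the
process (by arc direction), state variables and complex-member labels
are collected, units of information and stoichiometry are parsed but
ignored, and unknown glyph classes are skipped with a warning.  Two
EPNs denote one pool — and are merged — when they share class, label,
compartment, state decorations and complex-component labels; anonymous
EPNs (no label, decorations or components, and no clone marker) are
never merged, since an attribute-less node carries no evidence of
co-reference.  EPNs in different compartments always stay distinct.
Reversible processes are not detected (their notation is purely
spatial); rewrite them as two processes.

## Synthetic maps and what the tests show

`random_map` generates structurally valid maps (every process has some
flux or a source/sink flag; acyclic operators; no NOT) with tunable
counts, modulation density and operator probability, seeded for
reproducibility.  Default test sizes are 5 EPNs and 3 processes with
density 0.5 — small enough that every reachable state of 1000 maps can
be checked against the oracle in seconds, large enough to hit all four
transition rules, conflicts and unsatisfiable modulations.  These maps
emulate the combinatorics of real maps, not their biology: labels are
meaningless, there are no compartments, complexes or clone markers, and
modulation targets are uniform.  Passing tests therefore establish the
correctness of the encoding and the analyses, not the biological
adequacy of any particular map.

The reachability-transfer property (between process-quiescent states,
stories-semantics reachability implies general-semantics reachability
of the projected states) and the fixed-point transfer (a general fixed
point of projected form is fixed in the stories semantics) are verified
exhaustively on the worked example; they are not proved here in
general.  The converse direction is known to fail, and the mid-firing
states of the stories semantics may project outside the general STG —
the general semantics needs more intermediate steps for the same
overall move.

## Known limitations

* Explicit-state exploration only; no partial-order reduction, BDDs or
  unfoldings (delegate to external checkers via PNML).
* SBGN-AF/ER, SBML-qual export, CellDesigner import and reversible
  process detection are out of scope.
* Perturbing agents are treated as ordinary EPNs that modulate but are
  never produced or consumed.
* `cond(p)` grows exponentially with the number of story inhibitors per
  process (each absence literal expands to story-size many states);
  fine at desk scale, the dominant cost on heavily inhibited maps.
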