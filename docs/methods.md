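# Methods

This note records the semantics the package implements, the choices made
where the underlying constructions are genuinely open, and what the test
suite's synthetic systems do and do not establish.

## Reaction-system semantics

A reaction is a triple *(R, I, P)* with *R*, *P* nonempty and
*R ∩ I = ∅*.  The strict definition also requires *I* nonempty;
internally an empty inhibitor set is allowed, because the algebra of the
translations is cleaner without a mandatory dummy species.  The text
dialect offers a `strict` flag that rejects empty inhibitor fields, and
the serializer can re-insert a designated dummy inhibitor so files remain
strictly valid.  The result function is the plain union over enabled
reactions, so it is deterministic and independent of reaction iteration
order; species and reactions are kept in lexicographic order wherever
anything is serialized, making every artifact byte-reproducible.

Traces store `results[i] = Dᵢ` with `D₀ = ∅`; the full state
`Wᵢ = Dᵢ ∪ Cᵢ` is a derived accessor, never stored.  The final context of
a sequence influences nothing (the recurrence only reads `Cᵢ₋₁`), which
the simulators and all comparisons respect.

## Normal form and aliasing

Normalization enforces (1) single-product reactions and (2) products
disjoint from the context alphabet *Z*.  Product splitting is the obvious
per-product copy.  For a species *X* that is both context-supplied and
produced, a fresh alias `X__alias` takes over the produced role.  After
the rewrite, presence of the original *X* means "supplied by the
context" and presence of the alias means "produced last step"; a reaction
that tested *X* must behave as if either arrival form counts:

- **reactant occurrences** are duplicated over all replacement subsets
  (presence of either name enables — a disjunction, so parallel copies
  are correct);
- **inhibitor occurrences** put *both* names in the inhibitor set of a
  single reaction (presence of either name must inhibit — a conjunction
  of absences, so parallel copies would be wrong: one copy would fire
  whenever only one of the two forms is absent).

Only this asymmetric treatment makes the projection property hold — the
normalized trace, with aliases collapsed onto their originals, equals the
original trace for *every* context sequence over *Z*.  The property is
verified exhaustively on small instances (all context sequences of
length 4) and on randomized systems.  Input/output splitting
(`split_io`, for species that are simultaneously inputs and outputs of a
file without annotations) is the same rewrite with the roles mirrored:
the produced form keeps its name and the fresh `x_in` becomes the pure
input.  Both rewrites are exponential in the number of rewritten
reactants per reaction; normalization logs a warning past 10,000
reactions and splitting raises past a configurable cap with the advice to
annotate inputs and outputs manually.

## Translation choices

**RS → circuit.**  State variables are all non-input species, in
lexicographic order (published figures use various per-example bit
orders; an optional `label_order` reproduces them at presentation time).
Never-produced species used only as inhibitors ("dummy inhibitors") get
the constant-0 equation `d(t+1) = 0` — the empty DNF — which falls out of
the general rule (no reaction produces them).  Outputs are identity
projections `y(t) = y(t)` of the like-named state variables: the output
equation of the source formalism is read as exactly that projection.
Consequently the output caused by context `Cₜ` is visible at `t + 1`,
which is the reaction system's own timing.

**Circuit → RS.**  Every DNF conjunction becomes one reaction; a
conjunction with no negated literals receives a global dummy inhibitor
(never produced, never in a context, so it is permanently absent).  A
conjunction with *no positive literals* cannot become a reaction at all,
because reactant sets must be nonempty; such circuits are rejected with
an explicit error.  This is a real expressiveness boundary of the
construction, not an implementation shortcut — e.g. the classic two-bit
Mealy example contains the term `¬q1 ∧ ¬q2` and therefore has no direct
reaction-system image.  Identity output projections of a like-named state
variable are skipped (emitting a reaction `({y},{d},{y})` would wrongly
keep `y` alive one extra step); an output that *shares* a state
variable's name but is not its identity projection is rejected as
inconsistent naming.  The circuit's initial state becomes the first
context `C₀`, so round-tripped systems start from the right
configuration without special-casing.

**Round-trip timing.**  `circuit → RS → circuit` preserves state
trajectories exactly and output trajectories with a one-step delay (the
produced output symbol appears in the *next* result set).  The tests
compare `out₂[t+1] == out₁[t]` after feeding one trailing all-zero input;
both raw and delay-aligned comparisons are available to callers via
plain `simulate`.

## Mealy/Moore conventions

The Mealy automaton labels the edge leaving `(Q, x)` with
`G(Q, x)` — the truth-table reading, where the output column belongs to
the current state and input.  The Moore automaton (only for circuits
whose `G` reads no input) labels each node with `G(Q)` evaluated *at that
node*, matching how state-projection outputs are usually drawn (the node
label is the output).  Replaying the same input sequence, the Mealy
reading at step *t* equals the Moore entered-node reading at step
*t − 1*: the two disciplines carry the same values offset by exactly one
step, which is the "one-step output delay" between the presentations.
`StateAutomaton.run` implements both readings and the property is
asserted over random state-only-output circuits.  No state-splitting
Mealy↔Moore conversion is provided (out of scope), so a Moore request for
an input-dependent-output circuit is an error pointing at Mealy.

Automaton construction is a BFS closure over all `2ⁿ` input values from
the initial state (or from all `2ˢ` states in exhaustive mode) and is
therefore exponential; it refuses to run at ≥ 32 state variables or
> 16 inputs (configurable), the scale at which the graphs also stop
being readable.

## Verilog emission

Verilog-2001, one `always @(posedge clk)` block with nonblocking
assignments (so all registers update from pre-edge values — the
synchronous semantics), active-high synchronous reset loading the initial
state, outputs as continuous assignments; an output that is the identity
projection of a like-named state variable is the register itself
(declared `output` + `reg`), with no separate assign.  The test bench
drives inputs on the *falling* edge to keep stimulus changes away from
the sampling edge — a choice, since no timing discipline is prescribed by
the source formalism.  Identifier sanitization only has to dodge Verilog
keywords (species names are already identifier-shaped) and is checked to
be injective.

Correctness of the emitted text is established without an external
simulator: the next-state and output expressions are parsed back out of
the emitted module and re-evaluated against `step()` on every `(Q, X)`
combination of each fixture.  This checks the expression text itself;
simulator-level behaviour (event ordering, reset timing) is by
construction of the fixed template and is not separately exercised here.

## Synthetic systems and problem sizes

Random reaction systems are purely structural: uniformly drawn reactant,
inhibitor and product sets under validity constraints, with a reserved
never-produced input block.  They emulate nothing biological — no degree
distributions, no pathway motifs — so the property suites establish the
*algebraic* claims (translation faithfulness, projection, round-trip,
delay) on arbitrary structure, not performance or fit on real models.
Suite sizes: 200 random normal-form systems (≤ 10 species) for
translation faithfulness, 100 systems with multi-product and
context-overlapping reactions for normalization, all input sequences of
length ≤ 5 for round-trips at s + n ≤ 8, and a 246-species /
6720-reaction random system simulated for 1000 steps as a scale smoke
test — sized to mirror a published large signaling-pathway model while
keeping the whole suite interactive.  The set-based simulator is the
reference implementation; it favours clarity over speed and handles the
scale test in seconds, so no packed-bit backend is included.

## Known limitations

- Pure-negative DNF conjunctions have no reaction-system image (above).
- Normalization/splitting can blow up exponentially; caps warn or stop.
- No logic minimization and no automaton minimization: emitted circuits
  and graphs are the direct images of their sources, and optimization is
  deliberately left to external circuit tools.
- The text dialects are this package's own (documented in the module
  docstrings); no compatibility with any particular external simulator's
  input format is guaranteed.
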