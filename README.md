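# rescirc

**Reaction systems ↔ synchronous sequential circuits.**

Reaction systems are a qualitative modeling framework for biochemical
networks: a background set of species *S* and reactions *a = (R, I, P)*
that produce their products *P* exactly when all reactants *R* are present
and no inhibitor from *I* is.  A state is just a subset of *S*; nothing
persists unless actively produced (non-permanency), and the environment
injects a context set *Cᵢ* at every step:

```
D₀ = ∅,   Dᵢ = res_A(Dᵢ₋₁ ∪ Cᵢ₋₁),   res_A(X) = ⋃ { P : R ⊆ X, I ∩ X = ∅ }
```

This dynamics is exactly that of a synchronous sequential switching
circuit `Q(t+1) = F(Q(t), X(t)), Y(t) = G(Q(t), X(t))`: each produced
species *p* becomes a state bit whose next-state function, in disjunctive
normal form, has one conjunction per reaction producing *p* (reactants as
positive literals, inhibitors negated):

```
p(t+1) = ⋁_{(R,I,{p})}  ⋀_{r∈R} r(t) ∧ ⋀_{i∈I} ¬i(t)
```

`rescirc` implements this correspondence in both directions, for
modelers who want to analyze qualitative biological models with
circuit/automata tooling and for anyone who wants a hardware description
of a reaction system:

- parse/serialize a plain-text reaction-system dialect and a circuit
  equation format; simulate both (reference set-based semantics and
  bit-vector stepping);
- put systems in **normal form** (single-product reactions, products
  disjoint from contexts) with a behaviour-preserving alias construction;
- translate **RS → circuit** (with automatic input/output inference,
  dummy-inhibitor handling, and input/output splitting) and
  **circuit → RS** (one reaction per DNF conjunction, dummy inhibitors
  re-inserted, initial state becoming the first context);
- build **Mealy/Moore automata** of the dynamics and export GraphViz DOT;
- emit **Verilog-2001**: a synthesizable one-step-per-clock module and a
  test bench that feeds the context sequence.

## Worked example

The vimentin intermediate-filament self-assembly model: tetramers `T`
(supplied by the environment) assemble into octamers `O`, then
hexadecamers `H`, then filaments `F`, which persist; `d` is a dummy
inhibitor.  `examples/vimentin.rs` contains the four reactions and the
context sequence `{T}, ∅, ∅, ∅, ∅`:

```sh
$ rescirc compile examples/vimentin.rs -g --out out/
```

writes the circuit equations `out/vimentin.circ`:

```
#input T
#output F H O
#init 0000
F' = F & !d | H & !d
H' = O & !d
O' = T & !d
d' = 0
```

plus Verilog (`vimentin.v`, `vimentin_tb.v`), the Moore automaton
(`vimentin.dot`) and a run report (`vimentin_report.json`) saying
`"species": 5, "reactions": 4, "state_variables": 4, "automaton_nodes": 8,
"automaton_edges": 16` — 4 reactions became 4 state equations, and the
8 reachable states each have transitions for `T ∈ {0, 1}`.  In Python:

```python
>>> import rescirc as rc
>>> v = rc.vimentin_model()
>>> [sorted(d) for d in rc.run_process(v, [{"T"}, set(), set(), set(), set()]).results]
[[], ['O'], ['H'], ['F'], ['F']]
```

— a single pulse of tetramers ripples through octamer and hexadecamer to
a filament, which then sustains itself.  The Moore machine of the same
circuit has exactly one state that loops on itself while `T = 1`: label
`111` in `(F, H, O)` order, i.e., the fully assembled steady state.

The reverse direction turns the classic `1101` sequence-detector circuit
(`examples/detector.circ`) into six reactions over `{q1, q2, y, x, d}`,
and feeding the bits `1,1,0,1` as contexts makes `y` appear in `D₄` —
one step after the Mealy circuit emits it, which is precisely the
output-timing difference between the two models.

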