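"""Verilog emission: a synthesizable step module and a driving test bench.

The module computes one reaction-system step per rising clock edge: one
register per state variable, updated from the DNF next-state equations in
a single ``always @(posedge clk)`` block with an active-high synchronous
reset that loads the initial state; outputs are continuous assignments.
The test bench is non-synthesizable: it generates the clock, pulses reset,
applies one context (input vector) per cycle — driven on the falling edge
to keep stimuli away from the sampling edge — prints a line-per-cycle
trace via ``$display`` and writes a VCD dump.

Emission is a pure function of the circuit (byte-identical output for
identical circuits).  Verilog-2001 dialect, no board-specific I/O: input
and output circuitry must be integrated manually in a real design.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

from .circuit import DNF, SequentialCircuit
from .rs_core import ContextSequence, RSError
from .translate import TranslationError, contexts_to_inputs

# Verilog-2001 reserved words that valid species names could collide with.
_VERILOG_KEYWORDS = frozenset("""
always and assign automatic begin buf bufif0 bufif1 case casex casez cell
cmos config deassign default defparam design disable edge else end endcase
endconfig endfunction endgenerate endmodule endprimitive endspecify endtable
endtask event for force forever fork function generate genvar highz0 highz1
if ifnone incdir include initial inout input instance integer join large
liblist library localparam macromodule medium module nand negedge nmos nor
noshowcancelled not notif0 notif1 or output parameter pmos posedge primitive
pull0 pull1 pulldown pullup pulsestyle_ondetect pulsestyle_onevent rcmos
real realtime reg release repeat rnmos rpmos rtran rtranif0 rtranif1
scalared showcancelled signed small specify specparam strong0 strong1
supply0 supply1 table task time tran tranif0 tranif1 tri tri0 tri1 triand
trior trireg unsigned use vectored wait wand weak0 weak1 while wire wor
xnor xor
""".split())

_RESERVED_PORTS = frozenset({"clk", "rst"})


class EmitError(RSError):
    """A circuit cannot be rendered as Verilog."""


@dataclass(frozen=True)
class EmittedDesign:
    """Emitted Verilog sources plus the species → identifier port map."""

    module_text: str
    testbench_text: str
    port_map: dict[str, str]


def sanitize_identifiers(names: Iterable[str]) -> dict[str, str]:
    """Map variable names to unique, legal Verilog identifiers.

    Names are already identifier-shaped; collisions with Verilog keywords
    or the clock/reset ports get a ``_v`` suffix (with a counter if
    needed).  The mapping is injective or an :class:`EmitError` is raised.
    """
    mapping: dict[str, str] = {}
    used: set[str] = set(_RESERVED_PORTS)
    for name in names:
        candidate = name
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_$]*", candidate):
            raise EmitError(f"cannot sanitize identifier {name!r}")
        if candidate in _VERILOG_KEYWORDS or candidate in used:
            base = candidate + "_v"
            candidate = base
            counter = 1
            while candidate in used or candidate in _VERILOG_KEYWORDS:
                candidate = f"{base}{counter}"
                counter += 1
        mapping[name] = candidate
        used.add(candidate)
    return mapping


def _dnf_expr(f: DNF, rename: dict[str, str]) -> str:
    if not f.terms:
        return "1'b0"
    terms = []
    for t in f.sorted_terms():
        lits = [rename[v] for v in sorted(t.positive)] + \
               [f"~{rename[v]}" for v in sorted(t.negative)]
        terms.append("(" + " & ".join(lits) + ")" if lits else "1'b1")
    return " | ".join(terms)


def _port_map(circuit: SequentialCircuit) -> dict[str, str]:
    unique = list(dict.fromkeys(
        list(circuit.inputs) + list(circuit.states) + list(circuit.outputs)))
    return sanitize_identifiers(unique)


def _identity_outputs(circuit: SequentialCircuit) -> set[str]:
    """Outputs that are identity projections of a like-named state
    variable: the state register itself is the output port."""
    from .circuit import Conjunction
    identity = set()
    for y in circuit.outputs:
        if y in circuit.states:
            if circuit.output_fn[y] != DNF([Conjunction([y])]):
                raise EmitError(
                    f"output {y!r} shares a state variable's name but is "
                    f"not its identity projection")
            identity.add(y)
    return identity


def emit_module(circuit: SequentialCircuit,
                module_name: str = "rs_step") -> str:
    """Emit the synthesizable Verilog module for one step per clock."""
    port_map = _port_map(circuit)
    identity = _identity_outputs(circuit)
    inputs = [port_map[x] for x in circuit.inputs]
    outputs = [port_map[y] for y in circuit.outputs]
    ports = ["clk", "rst"] + inputs + outputs

    lines = [f"module {module_name}({', '.join(ports)});"]
    lines.append("  input clk, rst;")
    for x in inputs:
        lines.append(f"  input {x};")
    for y in outputs:
        lines.append(f"  output {y};")
    for q in circuit.states:
        lines.append(f"  reg {port_map[q]};")
    lines.append("")
    lines.append("  always @(posedge clk) begin")
    lines.append("    if (rst) begin")
    for q, bit in zip(circuit.states, circuit.initial_state):
        lines.append(f"      {port_map[q]} <= 1'b{bit};")
    lines.append("    end else begin")
    for q in circuit.states:
        expr = _dnf_expr(circuit.next_state[q], port_map)
        lines.append(f"      {port_map[q]} <= {expr};")
    lines.append("    end")
    lines.append("  end")
    lines.append("")
    for y in circuit.outputs:
        if y in identity:
            continue  # the state register itself drives the output port
        expr = _dnf_expr(circuit.output_fn[y], port_map)
        lines.append(f"  assign {port_map[y]} = {expr};")
    lines.append("endmodule")
    return "\n".join(lines) + "\n"


def emit_testbench(circuit: SequentialCircuit,
                   contexts: ContextSequence | Iterable[Iterable[str]],
                   module_name: str = "rs_step",
                   vcd_file: str = "trace.vcd") -> str:
    """Emit a non-synthesizable test bench applying one context per cycle.

    Context species must all be circuit inputs.  Inputs change on the
    falling clock edge; a ``$display`` line per cycle dumps the state and
    output registers; the run finishes after the last context.
    """
    if not isinstance(contexts, ContextSequence):
        contexts = ContextSequence(contexts)
    vectors = contexts_to_inputs(circuit, contexts)
    port_map = _port_map(circuit)
    inputs = [port_map[x] for x in circuit.inputs]
    outputs = [port_map[y] for y in circuit.outputs]
    state_refs = [f"dut.{port_map[q]}" for q in circuit.states]

    lines = [f"module {module_name}_tb;",
             "  reg clk = 0;",
             "  reg rst = 1;"]
    for x in inputs:
        lines.append(f"  reg {x} = 0;")
    for y in outputs:
        lines.append(f"  wire {y};")
    conn = ["    .clk(clk)", "    .rst(rst)"] + \
           [f"    .{x}({x})" for x in inputs] + \
           [f"    .{y}({y})" for y in outputs]
    lines.append(f"  {module_name} dut(")
    lines.append(",\n".join(conn))
    lines.append("  );")
    lines.append("")
    lines.append("  always #5 clk = ~clk;")
    lines.append("")
    fmt_state = " ".join("%b" for _ in circuit.states) or ""
    fmt_out = " ".join("%b" for _ in circuit.outputs) or ""
    display_args = ", ".join(["$time"] + state_refs + outputs)
    lines.append("  initial begin")
    lines.append(f'    $dumpfile("{vcd_file}");')
    lines.append(f"    $dumpvars(0, {module_name}_tb);")
    lines.append("    @(negedge clk);")
    lines.append("    rst = 0;")
    for vec in vectors:
        for x, bit in zip(inputs, vec):
            lines.append(f"    {x} = 1'b{bit};")
        lines.append("    @(negedge clk);")
        lines.append(
            f'    $display("t=%0t Q={fmt_state} Y={fmt_out}", '
            f"{display_args});")
    lines.append("    $finish;")
    lines.append("  end")
    lines.append("endmodule")
    return "\n".join(lines) + "\n"


def emit_design(circuit: SequentialCircuit,
                contexts: Optional[ContextSequence] = None,
                module_name: str = "rs_step") -> EmittedDesign:
    """Emit module + test bench (empty stimulus when no contexts given)."""
    if contexts is None:
        contexts = ContextSequence([])
    port_map = _port_map(circuit)
    return EmittedDesign(
        module_text=emit_module(circuit, module_name),
        testbench_text=emit_testbench(circuit, contexts, module_name),
        port_map=port_map)


# ---------------------------------------------------------------------------
# Text-level re-evaluation (simulator-free cross-check)
# ---------------------------------------------------------------------------

_ASSIGN_RE = re.compile(r"^\s*(?:assign\s+)?(\w+)\s*(?:<=|=)\s*(.+);$")


def parse_emitted_equations(module_text: str) -> dict[str, DNF]:
    """Parse the DNF expressions back out of an emitted module.

    Returns a mapping from (sanitized) register/output name to the DNF it
    is assigned, used to re-evaluate the emitted text against the source
    circuit without an external Verilog simulator.  Reset assignments
    (``1'b<bit>`` right-hand sides inside the reset branch) are skipped.
    """
    from .circuit import Conjunction

    equations: dict[str, DNF] = {}
    in_reset = False
    for line in module_text.splitlines():
        stripped = line.strip()
        if stripped.startswith("if (rst)"):
            in_reset = True
            continue
        if stripped.startswith("end else"):
            in_reset = False
            continue
        m = _ASSIGN_RE.match(line)
        if not m or in_reset:
            continue
        target, rhs = m.group(1), m.group(2).strip()
        if rhs == "1'b0":
            equations[target] = DNF.zero()
            continue
        if rhs == "1'b1":
            equations[target] = DNF.one()
            continue
        terms = []
        for term_text in rhs.split("|"):
            term_text = term_text.strip()
            if term_text.startswith("(") and term_text.endswith(")"):
                term_text = term_text[1:-1]
            positive, negative = [], []
            for lit in term_text.split("&"):
                lit = lit.strip()
                if lit.startswith("~"):
                    negative.append(lit[1:])
                else:
                    positive.append(lit)
            terms.append(Conjunction(positive, negative))
        equations[target] = DNF(terms)
    return equations
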