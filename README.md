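# darwinsim

A functional software simulator of the **Darwin3** neuromorphic chip
architecture: a 24×24 mesh of neuron cores, each time-multiplexing up to
4096 logical spiking neurons, programmed through a compact
domain-specific instruction set, wired through a compressed
axon-out/axon-in connectivity representation, and exchanging
address-event spike packets over an XY-routed network on chip.

The package is for computational-neuroscience and neuromorphic-systems
researchers who want to study, test or extend this class of
architecture on a workstation: write neuron/synapse/plasticity programs
in the chip's ISA, run them bit-exactly in fixed point, compress and
inspect connection topologies, and execute whole-chip spiking
applications such as on-chip-learning maze solving.

## The model family

Neuron cores execute two program sections per global time step
(inference, then learning) over a register file holding state variables,
parameters and traces in signed saturating fixed point (default Q8.8).
The supported dynamics are the discretised forms of standard models:

* **adaptive leaky integrate-and-fire** —
  `v(t+1) = p0·v + p1·I + p2·v_adp + c0`,
  `v_adp(t+1) = p3·v_adp + p4·v + c1`, with strict-threshold firing
  (`v > v_th`), reset to `v0` and spike-triggered adaptation `+c2`;
* **conductance-based dual-exponential synapse** —
  `h(t+1) = p8·h + Σ w·δ`, `g(t+1) = p5·g + p6·h`,
  `I(t+1) = g·v + p7·g` (delta and current-based synapses are the
  degenerate settings);
* **triplet, reward-modulated STDP** — traces
  `x0, y0, y1, r0` with per-spike increments and the three-term update
  `w(t+1) = w + P0*·r0·x0·y2 + P1*·r0·y0·x2 + P2*·r0·y1·x2`;
* Izhikevich, QIF and exponential IF through the state-dependent
  parameter pattern (`UPTTS` + `MOV`), and SDSP through compare/branch
  instructions.

Ten primary opcodes (`LSIS, LDIP, LSLS, LDLP, UPTIS, UPTVM, UPTLS,
UPTWT, UPTTS, GSPRS`) cover parallel load/store, the polynomial state
updates and spike generation; RISC-style extended instructions add
moves, compares, jumps and the shift/multiply/lookup-table microcode
behind division and exponentiation. Every model program is verified
**bit-for-bit** against an instruction-free reference implementation of
the same discrete equations — identical saturation, identical rounding,
step by step.

Connectivity is stored per core as axon-out chains (target node offset +
axon-in index, shared between neurons with identical chains) and typed
axon-in entries (full-core sequential weights, shared single weights,
group weight matrices, contiguous ranges, or points), giving per-core
fan-in/fan-out capacities of `(D1−1)·N` and `(D2−N)·N` for memory depths
`D1`, `D2` and `N` neurons.

## Worked example

```python
from darwinsim import assemble
from darwinsim.fixed_point import FixedPointFormat
from darwinsim.registers import RegisterFile
from darwinsim.timing import instruction_cycles
from darwinsim.programs import MODELS, lif_membrane_update
from darwinsim.verify import verify_model
from darwinsim.maze import generate_maze, solve_maze, bfs_oracle

# 1. assemble the two-instruction LIF listing
program = assemble("UPTVM 0xD\nGSPRS 0xA\n")
print("LIF program words:", [f"0x{w:04X}" for w in program.words()[0]])

# 2. cycle cost of the LIF membrane update
regs = RegisterFile(FixedPointFormat(), MODELS["lif"].registers)
print("LIF update cycles:", instruction_cycles(lif_membrane_update(), regs))

# 3. bit-exact check of the triplet-STDP program against its reference
steps = verify_model("stdp_triplet", steps=1000, seed=0)
print("triplet STDP: program == reference for", steps, "steps")

# 4. solve a maze with the on-chip plasticity rule
maze = generate_maze(31, 31, seed=7)
result = solve_maze(maze)
print("maze solved:", result.success,
      "| path length:", len(result.path),
      "| equals BFS shortest path:", result.path == bfs_oracle(maze))
```

prints

```
LIF program words: ['0x300D', '0x500A']
LIF update cycles: 4
triplet STDP: program == reference for 1000 steps
maze solved: True | path length: 129 | equals BFS shortest path: True
```

The two 16-bit words are the complete LIF inference program (opcode in
the top 5 bits, operand below). The 4-cycle figure comes from the
pipelined-multiplier timing model (two multiplications and two additions
in the membrane update). The maze result is produced by a genuine
whole-chip run: a spike wavefront launched at the start cell, STDP
potentiation of causal synapses, and a path read back from the learned
weights — matching the breadth-first-search oracle exactly.

A command-line interface wraps the same machinery:

```
darwinsim report capacity            # mesh/core/neuron/fan-in/out totals
darwinsim report density             # instruction counts per model program
darwinsim maze -W 15 -H 15 -S 3      # generate, solve and print a maze
darwinsim assemble prog.asm -o prog.bin
darwinsim run chip.yaml --steps 100 --out spikes.csv
```

## Layout

| module | contents |
| --- | --- |
| `darwinsim.isa` | instruction encoding, assembler/disassembler, DIV/EXP microcode expansion |
| `darwinsim.engine` | fixed-point neuron-core executor (inference, learning, events) |
| `darwinsim.models` | instruction-free reference implementations (the oracles) |
| `darwinsim.programs` | executable ISA programs for the model family |
| `darwinsim.verify` | bit-exact program-vs-reference verification driver |
| `darwinsim.connectivity` | compressed axon tables, capacity formulas, memory accounting |
| `darwinsim.noc` | XY-routed mesh, transmission latency, chip boundaries |
| `darwinsim.chip` | whole-chip runtime, YAML configuration, capacity report |
| `darwinsim.maze` | maze generation, network mapping, STDP solving |

See `docs/methods.md` for the modelling assumptions, numerical choices
and known limitations.
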