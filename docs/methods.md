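# Methods

This note records the modelling assumptions, numerical conventions and
design choices behind the simulator, in the order a reader meets them:
arithmetic, instruction set, execution engine, timing, connectivity,
routing, chip runtime, and the maze application.

## Fixed-point arithmetic

All neuron-core state lives in a signed, saturating two's-complement
fixed-point format, default Q8.8 (16 bits, 8 fractional). The format is
configurable per core (`total_bits`, `fraction_bits`); the Izhikevich
programs use 24-bit/12-fraction words because the quadratic membrane
term exceeds the Q8.8 range at biological parameter values.

Rounding conventions, applied consistently in both the instruction
engine and the reference models:

* the fused update datapath (UPTVM/UPTIS/UPTLS/UPTWT/UPTTS products)
  computes double-width products and **truncates** (arithmetic right
  shift, i.e. floor);
* the scalar extended multiplier (`MUL`) **rounds to nearest** (ties
  away from negative); this keeps the lookup-table microcode within one
  ULP;
* additions saturate at the format extremes; saturation is also the
  overflow behaviour of every register write (asserted in tests after
  every instruction).

Quantisation of real-valued parameters floors toward −∞. Spike flags are
stored as fixed-point 1.0, so flag-gated products are exact.

## Instruction set and encodings

A word is `opcode(5) | operand(11)`. The ten primary opcodes carry the
neuromorphic semantics; operand fields pack high-to-low in the
documented order (e.g. `UPTLS`: k(3)|l(3)|m(3)|n(2); `UPTWT`:
m(2)|nmask(9)); hot-mask bit *i* corresponds to register subscript *i*.
Unassigned ("reserve") bits are zero on encoding and ignored on
decoding, so bijectivity holds over the canonical word set (verified
exhaustively over all 2^16 words).

Extended instructions were given fixed opcodes in the unused 5-bit
space. Register–register forms pack the destination as a 6-bit index
into a unified 54-register space and the source as a 5-bit index; the
register order was chosen so that everything plausibly used as a source
(temporaries, state variables, traces, the weight, learning constants
LC0–LC3, inference constants) sits in the low 32 slots. `CMP` sets a
flag (`rd > rs`, signed); `JMP` is taken when the flag is set and resets
it, so a `JMP` not preceded by `CMP` is unconditional.

Some published example listings use operand encodings that no single
bit-order reconciles with the model equations (e.g. a LIF spike-stage
mask with two set bits where fire/compare/reset are needed). Those
listings are therefore kept verbatim as assembler/disassembler
round-trip fixtures, while the *executable* programs in
`darwinsim.programs` are built from the discrete equations with
semantically consistent masks. Both views are tested.

### DIV/EXP microcode

Division and exponentiation expand into shift/multiply/lookup sequences
over a 256-word ROM region of core memory: a 64-interval reciprocal
table on [1, 2) and a 64-interval exponential table on [−8, 0], both
linearly interpolated, each with endpoint and guard entries.

* `EXP` is within 1 ULP of a high-precision exponential across the
  domain grid (Q8.8).
* `DIV` normalises the divisor into [1, 2) with a shift loop, multiplies
  by the interpolated reciprocal, de-normalises, and applies one
  residual correction against the *original* divisor (the normalising
  shift truncates low divisor bits, so correcting in the normalised
  domain is not enough). Within the documented domain — divisor in
  [1, max), |dividend| at least one unit below the format maximum so the
  correction product cannot saturate — the result is within 1 ULP of
  exact floor division (verified on 1000 random pairs).

Both expansions clobber TR4–TR7 and one stack slot; operands must be
source-encodable and outside the clobber set. Shift immediates are
5-bit, which limits the expansions to formats with 3–12 (EXP) or 6–14
(DIV) fraction bits.

## Execution engine

Each logical neuron owns a full register file; the core holds the
shared two-section program, per-neuron input buffers, scratch/stack
memory and per-synapse learning records. One time step runs:

1. **fold** — `h ← p8·h + buffered input`, buffers cleared;
2. **inference** — the inference section per neuron, ascending ID;
3. **spike flags** — pre-synaptic flags (`x2`) were raised when the
   spike event was delivered; post-synaptic flags (`y2`) are raised on
   the firing neuron's incoming synapse records now;
4. **learning** — the learning section once per synapse with live
   learning state, ascending (post, pre), with LS0–LS9 and W overlaid
   from the synapse record; only LS0–LS9 and W are written back. Spike
   flags and the reward input last exactly one step.

Trace equations of the form `x(t+1) = P·x + C·flag` contain two
products, but `UPTLS` computes only `LP·LS + LC`; programs therefore
compose the increment from `MOV LS9, flag; MUL LS9, TRa; ADD LSk, LS9`
with the increment amplitudes held in TR4–TR7 and LC0 = 0 for the decay.
The published triplet listing places trace updates before the weight
updates, so the weight terms use the *updated* traces; engine and
reference both adopt that order (the printed equations index traces at
*t*, the hardware-order convention at *t+1*; the difference is a
one-step shift of the weight increments).

Learning state is **per synapse**: pre-trace, post-trace and reward
registers are all carried in the synapse record (post traces are thus
computed per synapse — redundant but simple, deterministic, and exactly
what the per-synapse reference computes). Reward input is a per-neuron
per-step value broadcast into `r2` during learning.

**Event-driven execution.** A neuron that received no input and whose
state is unchanged by a full step has reached a fixed point and goes
dormant until the next event; a synapse whose learning state is all
zero leaves the learning set. This is a pure optimisation: dormant
state is provably invariant, so trajectories are identical to the
always-run schedule (the bit-exact tests run both styles effectively,
since the references step every tick).

Parallel load/store instructions (LSIS/LDIP/LSLS/LDLP) are modelled as
single-step register-group syncs; because the simulator's register file
is itself the persistent per-neuron store, they are data-identical
no-ops that still cost one cycle each. A watchdog aborts any neuron
step that executes more than 4096 instructions (jumps allow
non-termination).

## Cycle-timing model

Multiplications take two cycles and additions one, with a pipelined
multiplier (two-cycle latency, one issue per cycle) and additions
overlapping multiplier occupancy:

```
cycles(M ≥ 1 multiplications, A ≥ 1 additions) = 2 + (M−1) + max(1, A−(M−1))
```

pure additions cost one cycle each, scalar instructions one cycle,
`MUL` two. This schedule reproduces both published anchors: the LIF
membrane update (2 mul + 2 add) costs 4 cycles and the CUBA Delta
update (1 mul + 1 add) costs 3. The two anchors are only consistent if
a product whose coefficient is exactly 1.0 does not occupy the
multiplier — a delta synapse adds the input current with `p1 = 1` — so
`cycle_count` optionally takes a register context and demotes
unity-coefficient products to addition-only terms. Without a register
context every masked product counts as a multiplication.

## Connectivity representation

Axon-out: per-neuron linkers point to chains of entries
`(target-node relative offset, axon-in index, last flag)`; neurons with
identical chains share one chain, with the linker carrying the neuron's
rank inside a shared source group. Axon-in: each received index selects
a typed entry — full-core sequential weights (1\*), shared single
index+weight (2\*), group index list with per-source weight rows (3\*),
contiguous range (4\*), or point. Case selection is greedy by
descending compression (full > range > group > shared > point); a
source whose rank in one group conflicts with an earlier assignment is
demoted to a private entry, which keeps the single per-neuron rank
consistent.

**Word model.** Memory is word-addressed with 64-bit words and 12-bit
neuron indexes. A linker occupies one word; an entry occupies
`ceil(bits/64)` words (minimum one) where the bits are its index part
plus any weight block it owns. Weight blocks are content-addressed in a
per-core pool, so identical rows (a convolution kernel seen by every
source) are stored once — this is what makes the convolutional mapping
cost approach the kernel parameter count plus index overhead. The
axon-in linker table sits outside the entry-word budget; one entry word
is reserved as a null pointer. Under this model the capacity formulas
`(D1−1)·N` fan-in and `(D2−N)·N` fan-out are exactly achievable for
small instances (N ≤ 4, 16-bit weights) and serve as a priori bounds in
general; physical word budgets are checked independently.

Two tile flavours differing in axon-in depth are exposed as a per-core
`D1` parameter (documented defaults 8 and 65537, spanning the quoted
fan-in range); the default axon-out depth is 16384.

Baseline mechanisms for memory comparison are deliberately simple
word-count rules (dense crossbar per active target core; one entry word
per synapse per side for flat indexing; a full N-weight row per source
link for population indexing) — they order mechanisms for the
comparative report and are not calibrated to any specific chip.

## Mesh routing

Packets carry the *relative* offset to their destination; routers
consume X before Y. Transmission delay through N routers is
`2N + 2(N+1)` cycles (the source router is counted, and there is one
more asynchronous interconnection than routers; local delivery is
N = 0, one crossing). Congestion is not modelled: routers forward one
packet per output per cycle with unbounded FIFOs, so delivery time is
exactly the path latency, and simultaneous arrivals order by (source
core, source neuron). Offsets that leave the mesh exit at an edge with
the residual offset unchanged and re-enter the neighbouring chip in the
same row/column lane — no address translation.

## Chip runtime

The global tick applies external stimuli, delivers every packet
injected during the previous step (the target core resolves its axon-in
entry to (neuron, weight) events), steps each core, and injects one
packet per (target core, axon-in index) for each fired neuron. Spike
delivery is therefore uniformly visible at the *next* step, for local
and remote targets alike; the cycle-level latency model is available
separately and does not reorder step-level delivery. This is the
simplest deterministic contract consistent with the event-plus-decay
structure of the synapse update; a latency-dependent same-step rule
would make intra-core neuron order observable and was rejected.

For cores in a learning mode, the per-synapse records are the
authoritative weight store: deliveries read the learned weight, so
plasticity feeds back into dynamics within one step.

Configuration is a YAML tree (mesh dimensions, per-core program text,
register values, depths, weight width, fixed-point format, connection
rows or a CSV path, stimuli); loading assembles programs, validates
coordinates and counts, and builds the connectivity tables so capacity
violations surface at load time. One time step nominally represents
1 ms of model time; nothing in the simulator depends on the absolute
scale.

## Maze application

`generate_maze` carves a depth-first spanning tree on the
odd-coordinate lattice (style `perfect`: free cells form a tree, so all
paths are unique; style `braided`: a fraction of removable walls is
opened to create loops). Start and goal are the first and last free
cells in row-major order. The generator emulates the study conditions —
randomly generated mazes of the published sizes — but not physical
sensor input or noisy stimulation; passing tests show the architecture
solves the idealized task, not robustness to input noise.

`maze_to_network` maps one neuron per cell (row-major, 4096 per core),
bidirectional 4-neighbour synapses of weight 1.0, and a wavefront LIF
program (`p0 = p1 = 1`, threshold 0.5, reset −8 so a fired cell cannot
re-fire from its remaining neighbours). Obstacles are neurons with an
unreachable threshold (120), so spikes terminate there. Learning is the
single instruction `w += 0.25·x2·y2`, which potentiates exactly the
synapses whose pre-neuron fired one step before the post-neuron — the
causal front of the wave. Every free cell therefore ends with
strengthened incoming edges only from breadth-first predecessors.

**Readout.** The path is read *backwards from the goal*, at each cell
following the strengthened incoming edge (tie-break N, E, S, W), then
reversed. A forward greedy walk over outgoing weights cannot work under
this rule: every branch of the wavefront — including dead ends —
strengthens equally, so outgoing weights carry no goal information,
whereas the incoming strengthened edge is the unique (on perfect mazes)
BFS predecessor. On braided mazes any strengthened predecessor lies on
*some* shortest path, so the readout still returns a shortest path.

The wavefront advances one cell per step (next-step delivery), so a
maze with BFS distance d is solved in d+1 steps; solvers use
`max_steps = W·H + 2`, which the distance bound guarantees. Sizing
beyond desk scale (e.g. 1534×1534 ≈ 2.35 M neurons) is reported from
metadata without building the network.

## Problem sizes used in the verification suite

* Bit-exact equivalence: 12 model programs × 10 seeds × 1000 steps.
* Connectivity round trips: 200 random graphs (32 neurons/core, mixed
  widths 1–16 bits, all five compression cases).
* NoC: exhaustive source/destination pairs on a 5×5 mesh plus a
  10,000-packet conservation load.
* Mazes: 50 perfect mazes, sizes 9×9 to 63×63 (plus braided and
  multi-core variants in the unit tests).
* Euler convergence: step sizes 0.4 → 0.025 against an adaptive
  high-precision ODE solution; observed order ≈ 1.

These sizes exercise every code path at full fidelity; larger meshes
and deeper tables change scale, not mechanism.

## Known limitations

* No congestion, virtual channels, or adaptive routing variants; the
  NoC is functionally correct, not performance-faithful.
* No energy/power modelling and no RISC-V management-node simulation
  (the management node only anchors coordinate (0,0)).
* Memory banking, ECC and clock-domain effects are not modelled;
  multi-frequency operation is collapsed onto a single network clock.
* Greedy (not optimal) compression-case selection; no ILP placement.
* The published example listings are encoding fixtures only where their
  operands are irreconcilable with the equations (see the ISA section).
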