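"""Neuron-core execution engine.

A neuron core time-multiplexes up to 4096 logical neurons.  Each neuron
owns a full :class:`~darwinsim.registers.RegisterFile`; the core holds the
shared program (an inference section and an optional learning section),
per-neuron input accumulation buffers, per-synapse learning state, and
the scratch/ROM memory behind the extended load/store instructions.

Execution per time step:

1. input buffers accumulated since the previous step are folded into the
   gating variable ``h`` (``h <- p8*h + buffered``), buffers cleared;
2. the inference section runs for every *active* neuron in ascending
   neuron ID; spikes are collected;
3. spike flags are raised (pre-synaptic flags were raised at delivery,
   post-synaptic flags now);
4. the learning section runs for every synapse with live learning state,
   in ascending (post, pre) order; spike flags and reward inputs are
   cleared.

The core is event driven: a neuron whose state is at a fixed point and
which receives no input is dormant and is skipped until woken by an
event, so silent cores perform no per-neuron work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

from .fixed_point import FixedPointFormat
from .isa.asm import Program
from .isa.instructions import Instruction
from .isa.pseudo import (
    ROM_SIZE,
    SCRATCH_BASE,
    SCRATCH_SIZE,
    STACK_TOP,
    build_microcode_rom,
    expand_pseudo,
)
from .registers import REG_INDEX, RegisterFile

MAX_NEURONS_PER_CORE = 4096
WATCHDOG_BUDGET = 4096  # executed instructions per neuron per phase

# frequently used register indices
_S = [REG_INDEX[f"S{i}"] for i in range(6)]
_IP = [REG_INDEX[f"IP{i}"] for i in range(9)]
_IC = [REG_INDEX[f"IC{i}"] for i in range(3)]
_LS = [REG_INDEX[f"LS{i}"] for i in range(10)]
_LP = [REG_INDEX[f"LP{i}"] for i in range(8)]
_LC = [REG_INDEX[f"LC{i}"] for i in range(8)]
_TR = [REG_INDEX[f"TR{i}"] for i in range(8)]
_W = REG_INDEX["W"]
_V0 = REG_INDEX["V0"]

# UPTIS one-hot targets
TARGET_VADP = 0b100
TARGET_G = 0b010
TARGET_I = 0b001

# GSPRS mask bits
SP_FIRE = 0b1000
SP_COMPARE = 0b0100
SP_ADAPT = 0b0010
SP_RESET = 0b0001


class EngineError(RuntimeError):
    pass


class WatchdogError(EngineError):
    pass


class MemoryFault(EngineError):
    pass


class RoutingFault(EngineError):
    pass


# ---------------------------------------------------------------------------
# Single-instruction update semantics (operate on one RegisterFile)
# ---------------------------------------------------------------------------

def exec_update_vm(regs: RegisterFile, mask: int) -> None:
    """v_m <- p0*v_m [b3] + p1*I [b2] + p2*v_adp [b1] + c0 [b0]."""
    fmt = regs.fmt
    acc = 0
    if mask & 0b1000:
        acc = fmt.add(acc, fmt.mul(regs.raw[_IP[0]], regs.raw[_S[0]]))
    if mask & 0b0100:
        acc = fmt.add(acc, fmt.mul(regs.raw[_IP[1]], regs.raw[_S[2]]))
    if mask & 0b0010:
        acc = fmt.add(acc, fmt.mul(regs.raw[_IP[2]], regs.raw[_S[4]]))
    if mask & 0b0001:
        acc = fmt.add(acc, regs.raw[_IC[0]])
    regs.raw[_S[0]] = acc


def exec_update_is(regs: RegisterFile, target: int, mask: int) -> None:
    """Update I, g or v_adp (one-hot target); terms gated by a 6-hot mask
    with bit0..bit4 = p3..p7 and bit5 = c1 (for the current update, bit5
    gates the parameter-free conductance-voltage product)."""
    fmt = regs.fmt
    acc = 0
    if target == TARGET_VADP:
        if mask & 0b000001:  # p3 * v_adp
            acc = fmt.add(acc, fmt.mul(regs.raw[_IP[3]], regs.raw[_S[4]]))
        if mask & 0b000010:  # p4 * v_m
            acc = fmt.add(acc, fmt.mul(regs.raw[_IP[4]], regs.raw[_S[0]]))
        if mask & 0b100000:  # + c1
            acc = fmt.add(acc, regs.raw[_IC[1]])
        regs.raw[_S[4]] = acc
    elif target == TARGET_G:
        if mask & 0b000100:  # p5 * g
            acc = fmt.add(acc, fmt.mul(regs.raw[_IP[5]], regs.raw[_S[1]]))
        if mask & 0b001000:  # p6 * h
            acc = fmt.add(acc, fmt.mul(regs.raw[_IP[6]], regs.raw[_S[3]]))
        regs.raw[_S[1]] = acc
    elif target == TARGET_I:
        if mask & 0b100000:  # g * v_m (conductance-voltage product)
            acc = fmt.add(acc, fmt.mul(regs.raw[_S[1]], regs.raw[_S[0]]))
        if mask & 0b010000:  # p7 * g
            acc = fmt.add(acc, fmt.mul(regs.raw[_IP[7]], regs.raw[_S[1]]))
        regs.raw[_S[2]] = acc
    else:
        raise EngineError(f"UPTIS target {target:#05b} is not one-hot")


def exec_update_ls(regs: RegisterFile, k: int, l: int, m: int, n: int) -> None:
    """LS_k <- LP_l * LS_m + LC_n."""
    if k > 9 or m > 9 or l > 7 or n > 3:
        raise EngineError(f"UPTLS field out of range: k={k} l={l} m={m} n={n}")
    fmt = regs.fmt
    val = fmt.add(fmt.mul(regs.raw[_LP[l]], regs.raw[_LS[m]]),
                  regs.raw[_LC[n]])
    regs.raw[_LS[k]] = val


def exec_update_wt(regs: RegisterFile, m: int, nmask: int) -> None:
    """W <- W + LP_m * prod(LS_i for set bits i of nmask).

    An empty selection leaves the weight unchanged.
    """
    if m > 3:
        raise EngineError(f"UPTWT m={m} out of range")
    if nmask == 0:
        return
    fmt = regs.fmt
    acc = regs.raw[_LP[m]]
    for i in range(9):
        if nmask & (1 << i):
            acc = fmt.mul(acc, regs.raw[_LS[i]])
    regs.raw[_W] = fmt.add(regs.raw[_W], acc)


def exec_update_ts(regs: RegisterFile, k: int, l: int, m: int, n: int) -> None:
    """TR_k <- p_l * S_m + c_n."""
    if k > 7 or l > 7 or m > 5 or n > 2:
        raise EngineError(f"UPTTS field out of range: k={k} l={l} m={m} n={n}")
    fmt = regs.fmt
    val = fmt.add(fmt.mul(regs.raw[_IP[l]], regs.raw[_S[m]]),
                  regs.raw[_IC[n]])
    regs.raw[_TR[k]] = val


def exec_gsprs(regs: RegisterFile, mask: int) -> bool:
    """Spike stage.  With threshold comparison enabled and v_m strictly
    above v_th: fire (if enabled), reset v_m to V0 (if enabled), add c2
    to v_adp (if enabled).  Without the comparison bit nothing happens."""
    if not mask & SP_COMPARE:
        return False
    if regs.raw[_S[0]] <= regs.raw[_S[5]]:
        return False
    spike = bool(mask & SP_FIRE)
    if mask & SP_ADAPT:
        regs.raw[_S[4]] = regs.fmt.add(regs.raw[_S[4]], regs.raw[_IC[2]])
    if mask & SP_RESET:
        regs.raw[_S[0]] = regs.raw[_V0]
    return spike


def apply_tick_decay(regs: RegisterFile, buffered: int = 0) -> None:
    """h <- p8 * h + buffered input (the event term of the gating update)."""
    fmt = regs.fmt
    regs.raw[_S[3]] = fmt.add(fmt.mul(regs.raw[_IP[8]], regs.raw[_S[3]]),
                              fmt.saturate(buffered))


# ---------------------------------------------------------------------------
# Extended-instruction execution frame
# ---------------------------------------------------------------------------

@dataclass
class _Frame:
    """Mutable execution context for one neuron's program run."""

    regs: RegisterFile
    rom: Dict[int, int]
    scratch: Dict[int, int]
    neuron: int
    time_step: int
    flag: bool = True
    ar: int = 0
    sp: int = STACK_TOP
    budget: int = WATCHDOG_BUDGET
    spike: bool = False

    def _mem_read(self, addr: int) -> int:
        if 0 <= addr < ROM_SIZE:
            return self.rom.get(addr, 0)
        if SCRATCH_BASE <= addr < STACK_TOP:
            return self.scratch.get(addr, 0)
        raise MemoryFault(
            f"neuron {self.neuron}: read from unmapped address {addr}")

    def _mem_write(self, addr: int, value: int) -> None:
        if SCRATCH_BASE <= addr < STACK_TOP:
            self.scratch[addr] = value
            return
        if 0 <= addr < ROM_SIZE:
            raise MemoryFault(
                f"neuron {self.neuron}: write to ROM address {addr}")
        raise MemoryFault(
            f"neuron {self.neuron}: write to unmapped address {addr}")


_EXPANSION_CACHE: Dict[Tuple[int, int, str, int, int], List[Instruction]] = {}


def _run_block(frame: _Frame, instructions: Sequence[Instruction]) -> None:
    fmt = frame.regs.fmt
    raw = frame.regs.raw
    pc = 0
    n = len(instructions)
    while pc < n:
        frame.budget -= 1
        if frame.budget < 0:
            raise WatchdogError(
                f"neuron {frame.neuron}: instruction budget of "
                f"{WATCHDOG_BUDGET} exhausted (unbounded jump loop?)")
        instr = instructions[pc]
        pc += 1
        m = instr.mnemonic
        if m == "UPTVM":
            exec_update_vm(frame.regs, instr["mask"])
        elif m == "UPTIS":
            exec_update_is(frame.regs, instr["target"], instr["mask"])
        elif m == "UPTLS":
            exec_update_ls(frame.regs, instr["k"], instr["l"],
                           instr["m"], instr["n"])
        elif m == "UPTWT":
            exec_update_wt(frame.regs, instr["m"], instr["nmask"])
        elif m == "UPTTS":
            exec_update_ts(frame.regs, instr["k"], instr["l"],
                           instr["m"], instr["n"])
        elif m == "GSPRS":
            if exec_gsprs(frame.regs, instr["mask"]):
                frame.spike = True
        elif m in ("LSIS", "LDIP", "LSLS", "LDLP"):
            # parallel register-group load/store between core memory and the
            # working registers; the simulator's register file is the
            # persistent store, so these are data-identical single steps
            pass
        elif m == "ADD":
            raw[instr["rd"]] = fmt.add(raw[instr["rd"]], raw[instr["rs"]])
        elif m == "SUB":
            raw[instr["rd"]] = fmt.sub(raw[instr["rd"]], raw[instr["rs"]])
        elif m == "MUL":
            raw[instr["rd"]] = fmt.mul_round(raw[instr["rd"]], raw[instr["rs"]])
        elif m == "ADDI":
            raw[instr["rd"]] = fmt.add(raw[instr["rd"]], instr["imm"])
        elif m == "SHIFT":
            raw[instr["rd"]] = fmt.shift(raw[instr["rd"]], instr["imm"])
        elif m == "LOGIC":
            raw[instr["rd"]] = fmt.saturate(raw[instr["rd"]] & raw[instr["rs"]])
        elif m in ("MOV", "WMOV"):
            raw[instr["rd"]] = raw[instr["rs"]]
        elif m == "CMP":
            frame.flag = raw[instr["rd"]] > raw[instr["rs"]]
        elif m == "JMP":
            if frame.flag:
                pc += instr["offset"]
                if not 0 <= pc <= n:
                    raise EngineError(
                        f"neuron {frame.neuron}: jump to {pc} leaves the "
                        f"program (length {n})")
            frame.flag = True
        elif m == "SA":
            frame.ar = raw[instr["rd"]]
        elif m == "TS":
            raw[instr["rd"]] = fmt.saturate(frame.time_step)
        elif m == "LOAD":
            raw[instr["rd"]] = frame._mem_read(frame.ar)
            frame.ar += 1
        elif m == "STORE":
            frame._mem_write(frame.ar, raw[instr["rd"]])
            frame.ar += 1
        elif m == "PUSH":
            frame.sp -= 1
            frame._mem_write(frame.sp, raw[instr["rd"]])
        elif m == "POP":
            raw[instr["rd"]] = frame._mem_read(frame.sp)
            frame.sp += 1
        elif m == "SP":
            frame.sp = raw[instr["rd"]]
        elif m in ("DIV", "EXP"):
            key = (fmt.total_bits, fmt.fraction_bits, m,
                   instr["rd"], instr["rs"])
            block = _EXPANSION_CACHE.get(key)
            if block is None:
                block = expand_pseudo(instr, fmt)
                _EXPANSION_CACHE[key] = block
            _run_block(frame, block)
        elif m == "NOP":
            pass
        else:  # pragma: no cover - registry and executor kept in sync
            raise EngineError(f"unimplemented mnemonic {m}")


# ---------------------------------------------------------------------------
# Core state
# ---------------------------------------------------------------------------

@dataclass
class SynapseState:
    """Per-synapse learning record held at the post-synaptic core."""

    weight: int          # raw fixed point
    width: int = 16      # stored weight width in bits
    ls: List[int] = field(default_factory=lambda: [0] * 10)


class NeuronCore:
    """State and executor for one neuron core (up to 4096 logical neurons)."""

    def __init__(self, neuron_count: int, program: Program,
                 fmt: FixedPointFormat | None = None,
                 mode: str = "inference",
                 coord: Tuple[int, int] = (0, 0)) -> None:
        if not 1 <= neuron_count <= MAX_NEURONS_PER_CORE:
            raise EngineError(
                f"core {coord}: neuron count {neuron_count} outside "
                f"1..{MAX_NEURONS_PER_CORE}")
        if mode not in ("inference", "learning", "both"):
            raise EngineError(f"core {coord}: unknown mode {mode!r}")
        if mode in ("learning", "both") and not program.learning:
            raise EngineError(
                f"core {coord}: learning mode requires a learning section")
        if not program.inference and mode != "learning":
            raise EngineError(
                f"core {coord}: inference mode requires an inference section")
        self.coord = coord
        self.neuron_count = neuron_count
        self.program = program
        self.fmt = fmt or FixedPointFormat()
        self.mode = mode
        self.registers: List[RegisterFile] = [
            RegisterFile(self.fmt) for _ in range(neuron_count)]
        self.rom = build_microcode_rom(self.fmt)
        self._scratch: Dict[int, Dict[int, int]] = {}
        self._buffers: Dict[int, int] = {}
        # incoming synapses: post neuron -> {pre key -> SynapseState}
        self.synapses: Dict[int, Dict[Tuple, SynapseState]] = {}
        self._live = set(range(neuron_count))
        self._pending_learning: set = set()  # (post, pre key)
        self._rewards: Dict[int, int] = {}
        self.time_step = 0

    # -- configuration ---------------------------------------------------
    def init_registers(self, values: Dict[str, float],
                       neurons: Optional[Iterable[int]] = None) -> None:
        targets = range(self.neuron_count) if neurons is None else neurons
        for n in targets:
            for name, value in values.items():
                self.registers[n][name] = value
            self._live.add(n)

    def add_synapse(self, pre_key, post: int, weight_raw: int,
                    width: int = 16,
                    ls_init: Optional[Dict[int, float]] = None) -> SynapseState:
        self._check_neuron(post)
        syn = SynapseState(weight=self.fmt.saturate(weight_raw), width=width)
        if ls_init:
            for idx, value in ls_init.items():
                syn.ls[idx] = self.fmt.quantize(value)
            if any(syn.ls):
                self._pending_learning.add((post, pre_key))
        self.synapses.setdefault(post, {})[pre_key] = syn
        return syn

    # -- event input -----------------------------------------------------
    def _check_neuron(self, neuron: int) -> None:
        if not 0 <= neuron < self.neuron_count:
            raise RoutingFault(
                f"core {self.coord}: neuron {neuron} outside configured "
                f"count {self.neuron_count}")

    def accumulate_input(self, neuron: int, weight_raw: int) -> None:
        """Add a weighted spike to the neuron's current-step input buffer."""
        self._check_neuron(neuron)
        self._buffers[neuron] = self._buffers.get(neuron, 0) + weight_raw
        self._live.add(neuron)

    def deliver_spike(self, pre_key, post: int,
                      weight_raw: Optional[int] = None) -> None:
        """Deliver one spike event: accumulate its weight and raise the
        pre-synaptic flag on the matching learning synapse (if any)."""
        self._check_neuron(post)
        syn = self.synapses.get(post, {}).get(pre_key)
        if syn is not None and self.mode in ("learning", "both"):
            syn.ls[2] = self.fmt.one  # x2: pre-spike flag
            self._pending_learning.add((post, pre_key))
            weight_raw = syn.weight  # learned weight is authoritative
        if weight_raw is None:
            raise RoutingFault(
                f"core {self.coord}: no weight for event {pre_key}->{post}")
        self.accumulate_input(post, weight_raw)

    def set_reward(self, neuron: int, value: float) -> None:
        self._check_neuron(neuron)
        self._rewards[neuron] = self.fmt.quantize(value)
        for pre_key in self.synapses.get(neuron, {}):
            self._pending_learning.add((neuron, pre_key))

    # -- execution -------------------------------------------------------
    def _run_section(self, neuron: int, section: Sequence[Instruction],
                     regs: RegisterFile) -> bool:
        frame = _Frame(regs=regs, rom=self.rom,
                       scratch=self._scratch.setdefault(neuron, {}),
                       neuron=neuron, time_step=self.time_step)
        _run_block(frame, section)
        return frame.spike

    def run_inference(self, neuron: int) -> bool:
        regs = self.registers[neuron]
        return self._run_section(neuron, self.program.inference, regs)

    def run_learning(self, neuron: int, pre_key) -> None:
        syn = self.synapses[neuron][pre_key]
        base = self.registers[neuron]
        work = base.copy()
        work.raw[_W] = syn.weight
        for i in range(10):
            work.raw[_LS[i]] = syn.ls[i]
        work.raw[_LS[8]] = self._rewards.get(neuron, 0)  # r2 input
        self._run_section(neuron, self.program.learning, work)
        syn.weight = work.raw[_W]
        syn.ls = [work.raw[_LS[i]] for i in range(10)]

    def run_program(self, neuron: int) -> bool:
        """Run inference then (in learning mode) learning for one neuron."""
        spiked = False
        if self.mode != "learning":
            spiked = self.run_inference(neuron)
            if spiked:
                self._raise_post_flags(neuron)
        if self.mode in ("learning", "both"):
            for pre_key in sorted(self.synapses.get(neuron, {}),
                                  key=repr):
                self.run_learning(neuron, pre_key)
        return spiked

    def _raise_post_flags(self, neuron: int) -> None:
        for pre_key, syn in self.synapses.get(neuron, {}).items():
            syn.ls[5] = self.fmt.one  # y2: post-spike flag
            self._pending_learning.add((neuron, pre_key))

    def step(self) -> List[int]:
        """Advance one time step; returns the ids of neurons that fired."""
        self.time_step += 1
        buffers, self._buffers = self._buffers, {}
        fired: List[int] = []
        run_inference = self.mode != "learning" and bool(self.program.inference)
        # phases 1+2: fold buffered input into h, then run inference, in
        # ascending neuron id over active neurons only.  A neuron whose
        # state is unchanged by a zero-input step has reached a fixed
        # point and goes dormant until the next event wakes it.
        for neuron in sorted(self._live):
            regs = self.registers[neuron]
            before = list(regs.raw)
            apply_tick_decay(regs, buffers.get(neuron, 0))
            spiked = self.run_inference(neuron) if run_inference else False
            if spiked:
                fired.append(neuron)
            elif regs.raw == before and neuron not in buffers:
                self._live.discard(neuron)
        # phase 3: post-synaptic spike flags
        if self.mode in ("learning", "both"):
            for neuron in fired:
                self._raise_post_flags(neuron)
            # phase 4: learning on synapses with live state
            done = []
            for post, pre_key in sorted(self._pending_learning, key=repr):
                self.run_learning(post, pre_key)
                syn = self.synapses[post][pre_key]
                syn.ls[2] = 0  # spike flags last exactly one step
                syn.ls[5] = 0
                syn.ls[8] = 0
                if not any(syn.ls):
                    done.append((post, pre_key))
            for key in done:
                self._pending_learning.discard(key)
            self._rewards.clear()
        return fired

    # -- inspection ------------------------------------------------------
    def dump_registers(self) -> List[Dict[str, float]]:
        return [regs.dump() for regs in self.registers]

    def weight(self, pre_key, post: int) -> float:
        syn = self.synapses.get(post, {}).get(pre_key)
        if syn is None:
            raise KeyError(f"no synapse {pre_key} -> {post}")
        return self.fmt.to_float(syn.weight)
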