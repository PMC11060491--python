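"""Cycle-timing model of the model-execution unit.

Multiplications take two cycles, additions one.  The multiplier is
pipelined (two-cycle latency, one issue per cycle) and chained additions
overlap multiplier occupancy, so an update with ``M >= 1`` multiplications
and ``A >= 1`` additions costs::

    2 + (M - 1) + max(1, A - (M - 1))

pure additions cost one cycle each, and scalar single-operation
instructions (moves, compares, branches, loads) cost one cycle.  A
product whose coefficient register holds exactly 1.0 is forwarded past
the multiplier and counts as an addition-only term; pass the register
context to enable this.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Union

from .isa.asm import Program
from .isa.instructions import Instruction
from .isa.pseudo import expand_pseudo
from .registers import REG_INDEX, RegisterFile

_ONE_CYCLE = {
    "LSIS", "LDIP", "LSLS", "LDLP", "GSPRS",
    "ADD", "SUB", "ADDI", "SHIFT", "LOGIC", "MOV", "WMOV",
    "CMP", "JMP", "SA", "TS", "LOAD", "STORE", "PUSH", "POP", "SP", "NOP",
}


def cycle_cost(n_mul: int, n_add: int) -> int:
    """Cycles for one update with the given multiplication/addition counts."""
    if n_mul < 0 or n_add < 0:
        raise ValueError("operation counts must be non-negative")
    if n_mul == 0:
        return max(n_add, 1)
    if n_add == 0:
        return 2 + (n_mul - 1)
    return 2 + (n_mul - 1) + max(1, n_add - (n_mul - 1))


def _is_unity(regs: Optional[RegisterFile], name: str) -> bool:
    return regs is not None and regs.get_raw(name) == regs.fmt.one


def _update_ops(instr: Instruction,
                regs: Optional[RegisterFile]) -> tuple[int, int]:
    """(multiplications, additions) performed by an update instruction."""
    m = instr.mnemonic
    if m == "UPTVM":
        mask = instr["mask"]
        terms = bin(mask & 0xF).count("1")
        muls = 0
        for bit, coef in ((0b1000, "IP0"), (0b0100, "IP1"), (0b0010, "IP2")):
            if mask & bit and not _is_unity(regs, coef):
                muls += 1
        return muls, max(terms - 1, 0)
    if m == "UPTIS":
        target, mask = instr["target"], instr["mask"]
        if target == 0b100:   # v_adp
            pairs = [(0b000001, "IP3"), (0b000010, "IP4")]
            const = bool(mask & 0b100000)
        elif target == 0b010:  # g
            pairs = [(0b000100, "IP5"), (0b001000, "IP6")]
            const = False
        else:                  # I
            pairs = [(0b010000, "IP7")]
            const = False
        muls = sum(1 for bit, coef in pairs
                   if mask & bit and not _is_unity(regs, coef))
        terms = sum(1 for bit, _ in pairs if mask & bit) + (1 if const else 0)
        if target == 0b001 and mask & 0b100000:  # g * v_m product
            muls += 1
            terms += 1
        return muls, max(terms - 1, 0)
    if m in ("UPTLS", "UPTTS"):
        coef = ("LP" if m == "UPTLS" else "IP") + str(instr["l"])
        muls = 0 if _is_unity(regs, coef) else 1
        return muls, 1
    if m == "UPTWT":
        nmask = instr["nmask"]
        factors = bin(nmask).count("1")
        if factors == 0:
            return 0, 0
        muls = factors
        if _is_unity(regs, f"LP{instr['m']}"):
            muls -= 1
        return muls, 1  # accumulate into the weight
    raise ValueError(f"{m} is not an update instruction")


def instruction_cycles(instr: Instruction,
                       regs: Optional[RegisterFile] = None) -> int:
    m = instr.mnemonic
    if m in ("UPTVM", "UPTIS", "UPTLS", "UPTWT", "UPTTS"):
        muls, adds = _update_ops(instr, regs)
        return cycle_cost(muls, adds)
    if m == "MUL":
        return 2
    if m in ("DIV", "EXP"):
        # straight-line cost of the shift/multiply/lookup expansion
        fmt = regs.fmt if regs is not None else None
        from .fixed_point import FixedPointFormat
        block = expand_pseudo(instr, fmt or FixedPointFormat())
        return sum(instruction_cycles(i, regs) for i in block)
    if m in _ONE_CYCLE:
        return 1
    raise ValueError(f"unknown mnemonic {m}")


def cycle_count(program: Union[Program, Sequence[Instruction]],
                regs: Optional[RegisterFile] = None) -> int:
    """Total cycles of a program (both sections) under the schedule above."""
    if isinstance(program, Program):
        instrs: Iterable[Instruction] = [*program.inference, *program.learning]
    else:
        instrs = program
    return sum(instruction_cycles(i, regs) for i in instrs)
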