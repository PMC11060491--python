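"""Pseudo-instruction expansion: DIV and EXP as shift/multiply/LUT microcode.

Division and exponentiation are not native operations; they expand into
finite sequences of SHIFT, MUL, ADD/SUB, CMP/JMP and table-lookup (SA/LOAD)
instructions over a small ROM region of core-local memory:

* addresses ``0..65``   — reciprocal table: ``1/x`` on ``[1, 2)``,
  64 intervals with linear interpolation (plus endpoint and guard entry);
* addresses ``128..194``— exponential table: ``exp(x)`` on ``[-8, 0]``,
  64 intervals with linear interpolation (plus endpoint and guard entry).

``EXP rd, rs``: rd <- exp(rs), domain rs in [-8, 0]; agrees with a
high-precision exponential within one ULP on that range.

``DIV rd, rs``: rd <- rd / rs; the divisor is normalised into [1, 2) by a
shift loop, a reciprocal-multiply gives the quotient, and one residual
correction against the original divisor tightens it.  Within the
documented domain — divisor in [1, max) and |dividend| at most one unit
below the format maximum, so that the correction product cannot
saturate — the result is within one ULP of exact floor division.

Both expansions clobber TR4..TR7 and the per-neuron stack top; ``rd`` and
``rs`` must be source-encodable registers outside TR4..TR7.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional

from ..fixed_point import FixedPointFormat
from ..registers import MAX_SOURCE_INDEX, REGISTER_NAMES
from .asm import assemble
from .instructions import Instruction

RECIP_BASE = 0
EXP_BASE = 128
EXP_XMIN = -8.0
EXP_BINS = 64
RECIP_BINS = 64
ROM_SIZE = 256
SCRATCH_BASE = ROM_SIZE
SCRATCH_SIZE = 256
STACK_TOP = SCRATCH_BASE + SCRATCH_SIZE


class PseudoExpansionError(ValueError):
    pass


def build_microcode_rom(fmt: FixedPointFormat) -> Dict[int, int]:
    """Raw ROM contents for a given fixed-point format (round-to-nearest)."""
    one = fmt.one
    rom: Dict[int, int] = {}
    for i in range(RECIP_BINS + 1):
        x = 1.0 + i / RECIP_BINS
        rom[RECIP_BASE + i] = fmt.saturate(round(one / x))
    rom[RECIP_BASE + RECIP_BINS + 1] = rom[RECIP_BASE + RECIP_BINS]  # guard
    span = -EXP_XMIN
    for i in range(EXP_BINS + 1):
        x = EXP_XMIN + i * span / EXP_BINS
        rom[EXP_BASE + i] = fmt.saturate(round(math.exp(x) * one))
    rom[EXP_BASE + EXP_BINS + 1] = rom[EXP_BASE + EXP_BINS]  # guard
    return rom


def _check_regs(instr: Instruction) -> tuple[str, str]:
    rd = REGISTER_NAMES[instr["rd"]]
    rs = REGISTER_NAMES[instr["rs"]]
    for r in (rd, rs):
        if r in ("TR4", "TR5", "TR6", "TR7"):
            raise PseudoExpansionError(
                f"{instr.mnemonic}: {r} is clobbered by the expansion")
    if instr["rd"] > MAX_SOURCE_INDEX:
        raise PseudoExpansionError(
            f"{instr.mnemonic}: destination {rd} must be source-encodable")
    return rd, rs


def expand_pseudo(instr: Instruction, fmt: FixedPointFormat | None = None,
                  divisor: Optional[float] = None) -> List[Instruction]:
    """Expand a DIV or EXP instruction into primitive instructions.

    ``divisor`` may supply a compile-time-known constant for DIV, enabling
    the exact single-SHIFT expansion for powers of two and the
    divide-by-zero diagnostic.
    """
    fmt = fmt or FixedPointFormat()
    if instr.mnemonic == "EXP":
        return _expand_exp(instr, fmt)
    if instr.mnemonic == "DIV":
        return _expand_div(instr, fmt, divisor)
    raise PseudoExpansionError(
        f"{instr.mnemonic} is not a pseudo instruction")


def _expand_exp(instr: Instruction, fmt: FixedPointFormat) -> List[Instruction]:
    rd, rs = _check_regs(instr)
    f = fmt.fraction_bits
    if not 3 <= f <= 12:
        raise PseudoExpansionError(
            "EXP expansion supports 3..12 fraction bits (shift immediates "
            "are 5-bit signed)")
    # bin width is 1/8 real = 2**(f-3) raw; fb = remainder << 3 in [0, 1)
    src = f"""
        MOV TR5, {rs}
        SUB TR6, TR6
        ADDI TR6, 1
        SHIFT TR6, {f + 3}
        ADD TR5, TR6          # t = x + 8
        MOV TR6, TR5
        SHIFT TR6, {-(f - 3)} # index
        MOV TR7, TR6
        SHIFT TR7, {f - 3}
        SUB TR5, TR7          # remainder
        SHIFT TR5, 3          # fraction-of-bin
        SUB TR7, TR7
        ADDI TR7, 1
        SHIFT TR7, 7          # table base 128
        ADD TR7, TR6
        SA TR7
        LOAD {rd}             # y0
        LOAD TR6              # y1
        SUB TR6, {rd}         # dy
        MUL TR6, TR5          # dy * fb
        ADD {rd}, TR6
    """
    return assemble(src).inference


def _expand_div(instr: Instruction, fmt: FixedPointFormat,
                divisor: Optional[float]) -> List[Instruction]:
    rd, rs = _check_regs(instr)
    f = fmt.fraction_bits
    if divisor is not None:
        if divisor == 0:
            raise PseudoExpansionError("division by zero immediate")
        log2 = math.log2(abs(divisor))
        if divisor > 0 and log2 == int(log2):
            return assemble(f"SHIFT {rd}, {-int(log2)}").inference
    if not 6 <= f <= 14:
        raise PseudoExpansionError(
            "DIV expansion supports 6..14 fraction bits (shift immediates "
            "are 5-bit signed)")
    src = f"""
        MOV TR4, {rd}         # a
        MOV TR5, {rs}         # b
        SUB TR7, TR7          # k = 0
        SUB TR6, TR6
        ADDI TR6, 1
        SHIFT TR6, {f + 1}    # 2.0
    Norm:
        CMP TR6, TR5          # b < 2 ?
        JMP Index
        SHIFT TR5, -1
        ADDI TR7, 1
        JMP Norm
    Index:
        PUSH TR7              # save k for the correction shift
        SUB TR6, TR6
        ADDI TR6, 1
        SHIFT TR6, {f}        # 1.0
        SUB TR5, TR6          # t = b_norm - 1 in [0, 1)
        MOV TR6, TR5
        SHIFT TR6, {-(f - 6)} # index in [0, 63]
        MOV {rd}, TR6
        SHIFT {rd}, {f - 6}
        SUB TR5, {rd}         # remainder
        SHIFT TR5, 6          # fraction-of-bin
        SA TR6
        LOAD {rd}             # y0
        LOAD TR6              # y1
        SUB TR6, {rd}         # dy
        MUL TR6, TR5          # dy * fb
        ADD TR6, {rd}         # r ~= 1/b_norm
        MOV {rd}, TR4
        MUL {rd}, TR6         # q ~= a * r  (normalised domain)
        SUB TR5, TR5          # zero
    Denorm:
        CMP TR7, TR5          # k > 0 ?
        JMP Shift1
        JMP Correct
    Shift1:
        SHIFT {rd}, -1
        ADDI TR7, -1
        JMP Denorm
    Correct:
        POP TR7               # k
        MOV TR5, {rd}
        MUL TR5, {rs}         # q * b (the original divisor)
        SUB TR4, TR5          # residual = a - q*b
        MUL TR4, TR6          # residual * r
        SUB TR5, TR5          # zero
    Shift2:
        CMP TR7, TR5          # k > 0 ?
        JMP Shift2b
        JMP Done
    Shift2b:
        SHIFT TR4, -1
        ADDI TR7, -1
        JMP Shift2
    Done:
        ADD {rd}, TR4         # corrected quotient
    """
    return assemble(src).inference
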