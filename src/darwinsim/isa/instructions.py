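"""Instruction words, field layouts and bit-exact encode/decode.

Every instruction is one 16-bit word: a 5-bit opcode and an 11-bit
operand.  Ten *primary* opcodes carry the neuromorphic update semantics
(parallel load/store of register groups, polynomial state updates, spike
generation); the *extended* opcodes add RISC-style scalar operations used
for control flow, register moves and the shift/multiply/lookup microcode
behind division and exponentiation.

Operand fields are packed high-to-low in the documented left-to-right
order; hot-mask bit ``i`` corresponds to the register with subscript
``i``.  Unassigned ("reserve") operand bits are zero after encoding and
ignored on decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

OPCODE_BITS = 5
OPERAND_BITS = 11
WORD_BITS = OPCODE_BITS + OPERAND_BITS
OPERAND_MASK = (1 << OPERAND_BITS) - 1


class EncodeError(ValueError):
    """A field does not fit its declared width."""


class DecodeError(ValueError):
    """The word's opcode is not registered."""

    def __init__(self, word: int, message: str) -> None:
        super().__init__(message)
        self.word = word


@dataclass(frozen=True)
class InstructionWord:
    """A 16-bit encoded instruction word."""

    value: int

    def __post_init__(self) -> None:
        if not 0 <= self.value < (1 << WORD_BITS):
            raise EncodeError(f"word {self.value:#x} does not fit 16 bits")

    @property
    def opcode(self) -> int:
        return self.value >> OPERAND_BITS

    @property
    def operand(self) -> int:
        return self.value & OPERAND_MASK


# ---------------------------------------------------------------------------
# Field layout descriptions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Field:
    name: str
    width: int
    shift: int
    signed: bool = False

    def pack(self, value: int) -> int:
        lo = -(1 << (self.width - 1)) if self.signed else 0
        hi = (1 << (self.width - 1)) - 1 if self.signed else (1 << self.width) - 1
        if not lo <= value <= hi:
            raise EncodeError(
                f"field {self.name!r} value {value} does not fit "
                f"{self.width} bits ({'signed' if self.signed else 'unsigned'})")
        return (value & ((1 << self.width) - 1)) << self.shift

    def unpack(self, operand: int) -> int:
        raw = (operand >> self.shift) & ((1 << self.width) - 1)
        if self.signed and raw >= (1 << (self.width - 1)):
            raw -= 1 << self.width
        return raw


def _layout(*fields: Tuple) -> Tuple[Field, ...]:
    return tuple(Field(*f) for f in fields)


# Primary instructions -------------------------------------------------------
# name -> (opcode, fields)
_PRIMARY: Dict[str, Tuple[int, Tuple[Field, ...]]] = {
    # parallel load/store of the six inference state variables S0..S5
    "LSIS": (0x01, _layout(("ls", 1, 10), ("mask", 6, 0))),
    # parallel load of inference parameters p0..p7 and constants c0..c2
    "LDIP": (0x02, _layout(("pmask", 8, 3), ("cmask", 3, 0))),
    # parallel load/store of the learning state variables LS0..LS9
    "LSLS": (0x03, _layout(("ls", 1, 10), ("mask", 10, 0))),
    # parallel load of learning parameters LP0..LP6 and constants LC0..LC3
    "LDLP": (0x04, _layout(("pmask", 7, 4), ("cmask", 4, 0))),
    # update I, g or v_adp (one-hot target), terms gated by a 6-hot mask
    # over {p3, p4, p5, p6, p7, c1} (bit 0 = p3 .. bit 4 = p7, bit 5 = c1)
    "UPTIS": (0x05, _layout(("target", 3, 6), ("mask", 6, 0))),
    # update v_m; 4-hot mask bit3=v_m, bit2=I, bit1=v_adp, bit0=c0
    "UPTVM": (0x06, _layout(("mask", 4, 0),)),
    # LS_k <- LP_l * LS_m + LC_n
    "UPTLS": (0x07, _layout(("k", 3, 8), ("l", 3, 5), ("m", 3, 2), ("n", 2, 0))),
    # W <- W + LP_m * prod(LS_n over 9-hot mask over LS0..LS8)
    "UPTWT": (0x08, _layout(("m", 2, 9), ("nmask", 9, 0))),
    # TR_k <- p_l * S_m + c_n
    "UPTTS": (0x09, _layout(("k", 3, 8), ("l", 3, 5), ("m", 3, 2), ("n", 2, 0))),
    # spike stage; 4-hot mask bit3=fire, bit2=compare, bit1=adapt, bit0=reset
    "GSPRS": (0x0A, _layout(("mask", 4, 0),)),
}

# Extended instructions -------------------------------------------------------
# Register-register ops pack rd (6-bit unified index) high, rs (5-bit) low.
_RD_RS = _layout(("rd", 6, 5), ("rs", 5, 0))
_RD_IMM = _layout(("rd", 6, 5), ("imm", 5, 0, True))
_RD = _layout(("rd", 6, 5))

_EXTENDED: Dict[str, Tuple[int, Tuple[Field, ...]]] = {
    "NOP": (0x00, _layout()),
    "ADD": (0x10, _RD_RS),
    "SUB": (0x11, _RD_RS),
    "MUL": (0x12, _RD_RS),
    "ADDI": (0x13, _RD_IMM),
    "SHIFT": (0x14, _RD_IMM),
    "LOGIC": (0x15, _RD_RS),        # bitwise AND of raw values
    "MOV": (0x16, _RD_RS),
    "WMOV": (0x17, _RD_RS),         # move through the weight port
    "CMP": (0x18, _RD_RS),          # flag <- (rd > rs), signed
    "JMP": (0x19, _layout(("offset", 11, 0, True))),
    "SA": (0x1A, _RD),              # address register <- raw(rd)
    "TS": (0x1B, _RD),              # rd <- current time step (raw)
    "LOAD": (0x1C, _RD),            # rd <- mem[AR]; AR += 1
    "STORE": (0x1D, _RD),           # mem[AR] <- rd; AR += 1
    "PUSH": (0x1E, _RD),
    "POP": (0x1F, _RD),
    "SP": (0x0C, _RD),              # stack pointer <- raw(rd)
    # pseudo operations: directly executable, and expandable to
    # shift/multiply/lookup sequences via expand_pseudo()
    "DIV": (0x0E, _RD_RS),
    "EXP": (0x0F, _RD_RS),
}

PRIMARY_MNEMONICS = tuple(_PRIMARY)
EXTENDED_MNEMONICS = tuple(_EXTENDED)
PSEUDO_MNEMONICS = ("DIV", "EXP")

_ALL: Dict[str, Tuple[int, Tuple[Field, ...]]] = {**_PRIMARY, **_EXTENDED}
_BY_OPCODE: Dict[int, str] = {}
for _name, (_op, _fields) in _ALL.items():
    if _op in _BY_OPCODE:
        raise RuntimeError(f"duplicate opcode {_op:#x}")
    _BY_OPCODE[_op] = _name


@dataclass(frozen=True)
class Instruction:
    """A decoded instruction: mnemonic plus its named operand fields."""

    mnemonic: str
    fields: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mnemonic not in _ALL:
            raise EncodeError(f"unknown mnemonic {self.mnemonic!r}")
        object.__setattr__(self, "fields", dict(self.fields))
        declared = {f.name for f in _ALL[self.mnemonic][1]}
        unknown = set(self.fields) - declared
        if unknown:
            raise EncodeError(
                f"{self.mnemonic}: unknown fields {sorted(unknown)}")

    def __getitem__(self, name: str) -> int:
        return self.fields.get(name, 0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Instruction):
            return NotImplemented
        if self.mnemonic != other.mnemonic:
            return False
        names = {f.name for f in _ALL[self.mnemonic][1]}
        return all(self[n] == other[n] for n in names)

    def __hash__(self) -> int:
        names = sorted(f.name for f in _ALL[self.mnemonic][1])
        return hash((self.mnemonic, tuple(self[n] for n in names)))

    def __repr__(self) -> str:
        inner = ", ".join(f"{k}={v:#x}" for k, v in self.fields.items())
        return f"{self.mnemonic}({inner})"


def instruction_fields(mnemonic: str) -> Tuple[Field, ...]:
    return _ALL[mnemonic][1]


def is_primary(mnemonic: str) -> bool:
    return mnemonic in _PRIMARY


def encode_instruction(instr: Instruction) -> InstructionWord:
    """Pack an :class:`Instruction` into its unique 16-bit word."""
    opcode, fields = _ALL[instr.mnemonic]
    operand = 0
    for f in fields:
        operand |= f.pack(instr.fields.get(f.name, 0))
    return InstructionWord((opcode << OPERAND_BITS) | operand)


def decode_instruction(word: InstructionWord | int) -> Instruction:
    """Inverse of :func:`encode_instruction`; reserve bits are ignored."""
    if isinstance(word, int):
        word = InstructionWord(word)
    name = _BY_OPCODE.get(word.opcode)
    if name is None:
        raise DecodeError(word.value,
                          f"invalid instruction word {word.value:#06x}: "
                          f"opcode {word.opcode:#04x} is not registered")
    _, fields = _ALL[name]
    values = {f.name: f.unpack(word.operand) for f in fields}
    return Instruction(name, values)


def raw_word(mnemonic: str, operand: int) -> InstructionWord:
    """Build a word from a mnemonic and a raw 11-bit operand literal."""
    if mnemonic not in _ALL:
        raise EncodeError(f"unknown mnemonic {mnemonic!r}")
    if not 0 <= operand <= OPERAND_MASK:
        raise EncodeError(f"operand {operand:#x} does not fit 11 bits")
    return InstructionWord((_ALL[mnemonic][0] << OPERAND_BITS) | operand)


def valid_field_values(mnemonic: str) -> List[Dict[str, List[int]]]:
    """Per-field value ranges, used by exhaustive round-trip tests."""
    out = []
    for f in _ALL[mnemonic][1]:
        if f.signed:
            lo, hi = -(1 << (f.width - 1)), (1 << (f.width - 1)) - 1
        else:
            lo, hi = 0, (1 << f.width) - 1
        out.append({f.name: list(range(lo, hi + 1))})
    return out
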