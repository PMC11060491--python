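"""Two-pass assembler and disassembler.

Source format: one instruction per line, ``MNEMONIC operand``.  The
operand is either a raw hex/decimal literal (primary instructions are
conventionally written this way, e.g. ``UPTVM 0xD``) or symbolic register
names for the extended instructions (``MOV P0, RT0``).  Labels end with a
colon and may share a line with an instruction; jump targets resolve
case-insensitively to relative offsets.  ``.inference`` and ``.learning``
directives switch the target program section.

Binary program files are little-endian 16-bit words preceded by a
two-entry header holding the section lengths.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import BinaryIO, Dict, Iterable, List, Tuple

from ..registers import MAX_SOURCE_INDEX, REGISTER_NAMES, resolve_register
from .instructions import (
    DecodeError,
    Instruction,
    InstructionWord,
    decode_instruction,
    encode_instruction,
    instruction_fields,
    raw_word,
)


class AssemblyError(ValueError):
    def __init__(self, message: str, line: int | None = None) -> None:
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass
class Program:
    """An ordered pair of instruction sections: inference then learning."""

    inference: List[Instruction] = field(default_factory=list)
    learning: List[Instruction] = field(default_factory=list)

    def words(self) -> Tuple[List[int], List[int]]:
        return ([encode_instruction(i).value for i in self.inference],
                [encode_instruction(i).value for i in self.learning])

    def __len__(self) -> int:
        return len(self.inference) + len(self.learning)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Program):
            return NotImplemented
        return self.words() == other.words()


_SYMBOLIC = {"ADD", "SUB", "MUL", "LOGIC", "MOV", "WMOV", "CMP",
             "DIV", "EXP", "SA", "TS", "LOAD", "STORE", "PUSH", "POP", "SP"}
_IMM_OPS = {"ADDI", "SHIFT"}


def _parse_int(token: str, line: int) -> int:
    token = token.replace("×", "x")  # typographic multiplication sign
    try:
        if token.lower().startswith("0x"):
            return int(token, 16)
        if token.lower().startswith("-0x"):
            return -int(token[1:], 16)
        return int(token, 10)
    except ValueError:
        raise AssemblyError(f"malformed operand {token!r}", line) from None


def _tokenize(text: str) -> List[Tuple[int, List[str]]]:
    out = []
    for lineno, rawline in enumerate(text.splitlines(), start=1):
        code = rawline.split("#", 1)[0].split(";", 1)[0].strip()
        if not code:
            continue
        tokens = code.replace(",", " ").split()
        out.append((lineno, tokens))
    return out


def assemble(text: str) -> Program:
    """Assemble source text into a :class:`Program`.

    Raises :class:`AssemblyError` with the offending line number for
    unknown mnemonics, malformed operands or undefined labels.
    """
    # pass 1: collect (section, lineno, tokens) per instruction + labels
    section = "inference"
    items: List[Tuple[str, int, List[str]]] = []
    labels: Dict[str, Tuple[str, int]] = {}
    counts = {"inference": 0, "learning": 0}
    for lineno, tokens in _tokenize(text):
        while tokens and tokens[0].endswith(":"):
            label = tokens[0][:-1].lower()
            if not label:
                raise AssemblyError("empty label", lineno)
            if label in labels:
                raise AssemblyError(f"duplicate label {label!r}", lineno)
            labels[label] = (section, counts[section])
            tokens = tokens[1:]
        if not tokens:
            continue
        head = tokens[0].lower()
        if head in (".inference", ".learning"):
            if len(tokens) > 1:
                raise AssemblyError("directive takes no operands", lineno)
            section = head[1:]
            continue
        items.append((section, lineno, tokens))
        counts[section] += 1

    # pass 2: encode
    program = Program()
    positions = {"inference": 0, "learning": 0}
    for sec, lineno, tokens in items:
        instr = _assemble_one(tokens, lineno, labels, sec, positions[sec])
        getattr(program, sec).append(instr)
        positions[sec] += 1
    return program


def _assemble_one(tokens: List[str], lineno: int,
                  labels: Dict[str, Tuple[str, int]],
                  section: str, position: int) -> Instruction:
    mnemonic = tokens[0].upper()
    args = tokens[1:]
    try:
        fields = instruction_fields(mnemonic)
    except KeyError:
        raise AssemblyError(f"unknown mnemonic {tokens[0]!r}", lineno) from None

    if mnemonic == "NOP":
        if args:
            raise AssemblyError("NOP takes no operands", lineno)
        return Instruction("NOP")

    if mnemonic == "JMP":
        if len(args) != 1:
            raise AssemblyError("JMP takes one operand", lineno)
        tok = args[0]
        if tok.lower() in labels:
            tsec, tpos = labels[tok.lower()]
            if tsec != section:
                raise AssemblyError(
                    f"label {tok!r} is in the {tsec} section", lineno)
            offset = tpos - (position + 1)
        else:
            try:
                offset = _parse_int(tok, lineno)
            except AssemblyError:
                raise AssemblyError(f"undefined label {tok!r}", lineno) from None
        try:
            return Instruction("JMP", {"offset": offset})
        except ValueError as exc:
            raise AssemblyError(str(exc), lineno) from None

    # single raw numeric operand -> raw word (canonical for primary opcodes)
    if len(args) == 1 and _looks_numeric(args[0]):
        operand = _parse_int(args[0], lineno)
        try:
            return decode_instruction(raw_word(mnemonic, operand))
        except (ValueError, DecodeError) as exc:
            raise AssemblyError(str(exc), lineno) from None

    if mnemonic in _SYMBOLIC or mnemonic in _IMM_OPS:
        want = len(fields)
        if len(args) != want:
            raise AssemblyError(
                f"{mnemonic} takes {want} operand(s), got {len(args)}", lineno)
        values = {}
        for f, tok in zip(fields, args):
            if f.name in ("imm",):
                values[f.name] = _parse_int(tok, lineno)
            else:
                try:
                    idx = resolve_register(tok)
                except KeyError as exc:
                    raise AssemblyError(str(exc), lineno) from None
                if f.name == "rs" and idx > MAX_SOURCE_INDEX:
                    raise AssemblyError(
                        f"register {tok!r} (index {idx}) cannot be encoded "
                        f"as a source operand (5-bit field)", lineno)
                values[f.name] = idx
        try:
            return Instruction(mnemonic, values)
        except ValueError as exc:
            raise AssemblyError(str(exc), lineno) from None

    raise AssemblyError(
        f"malformed operand {' '.join(args)!r}: {mnemonic} expects a "
        f"single numeric operand", lineno)


def _looks_numeric(token: str) -> bool:
    t = token.replace("×", "x").lower().lstrip("-")
    return t.startswith("0x") or t.isdigit()


# ---------------------------------------------------------------------------
# Disassembly
# ---------------------------------------------------------------------------

def _format_instruction(instr: Instruction) -> str:
    m = instr.mnemonic
    if m == "NOP":
        return "NOP"
    if m == "JMP":
        return f"JMP {instr['offset']}"
    names = [f.name for f in instruction_fields(m)]
    if set(names) <= {"rd", "rs", "imm"}:
        parts = []
        for n in names:
            if n == "imm":
                parts.append(str(instr["imm"]))
            else:
                parts.append(REGISTER_NAMES[instr[n]])
        return f"{m} " + ", ".join(parts)
    # primary opcodes: canonical raw hex operand
    word = encode_instruction(instr)
    return f"{m} 0x{word.operand:X}"


def disassemble(program: Program) -> str:
    """Render a program as source text; assembling it reproduces the
    program word-for-word."""
    lines: List[str] = []
    if program.inference or program.learning:
        if program.learning:
            lines.append(".inference")
    for instr in program.inference:
        lines.append(_format_instruction(instr))
    if program.learning:
        lines.append(".learning")
        for instr in program.learning:
            lines.append(_format_instruction(instr))
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Binary program files
# ---------------------------------------------------------------------------

def write_program(program: Program, fh: BinaryIO) -> None:
    inf, lrn = program.words()
    fh.write(struct.pack("<HH", len(inf), len(lrn)))
    for w in inf + lrn:
        fh.write(struct.pack("<H", w))


def read_program(fh: BinaryIO) -> Program:
    header = fh.read(4)
    if len(header) != 4:
        raise AssemblyError("truncated program header")
    n_inf, n_lrn = struct.unpack("<HH", header)
    body = fh.read(2 * (n_inf + n_lrn))
    if len(body) != 2 * (n_inf + n_lrn):
        raise AssemblyError("truncated program body")
    words = struct.unpack(f"<{n_inf + n_lrn}H", body)
    return Program(
        [decode_instruction(InstructionWord(w)) for w in words[:n_inf]],
        [decode_instruction(InstructionWord(w)) for w in words[n_inf:]],
    )
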