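"""Instruction encoding, assembly and disassembly."""

import io
import itertools

import numpy as np
import pytest

from darwinsim.isa import (
    AssemblyError,
    DecodeError,
    EncodeError,
    Instruction,
    InstructionWord,
    MODEL_LISTINGS,
    PRIMARY_MNEMONICS,
    Program,
    assemble,
    decode_instruction,
    disassemble,
    encode_instruction,
    read_program,
    write_program,
)
from darwinsim.isa.examples import MODEL_LISTING_LENGTHS
from darwinsim.isa.instructions import (
    instruction_fields,
    raw_word,
    valid_field_values,
)


def _reserve_mask(mnemonic: str) -> int:
    used = 0
    for f in instruction_fields(mnemonic):
        used |= ((1 << f.width) - 1) << f.shift
    return 0x7FF & ~used


def test_exhaustive_word_bijectivity():
    """Over all 2^16 words: registered opcodes decode, re-encode with
    reserve bits cleared, and decode back to the same instruction."""
    decodable = 0
    for value in range(1 << 16):
        try:
            instr = decode_instruction(InstructionWord(value))
        except DecodeError:
            continue
        decodable += 1
        word = encode_instruction(instr)
        reserve = _reserve_mask(instr.mnemonic)
        assert word.operand & reserve == 0
        assert word.value == value & ~reserve
        assert decode_instruction(word) == instr
    assert decodable > 0


@pytest.mark.parametrize("mnemonic", ["UPTVM", "GSPRS", "UPTLS", "UPTWT",
                                      "LSIS", "LDIP", "ADD", "JMP", "ADDI"])
def test_field_sweep_roundtrip(mnemonic):
    """Every valid field combination encodes and decodes to itself."""
    ranges = [list(d.values())[0] for d in valid_field_values(mnemonic)]
    names = [list(d.keys())[0] for d in valid_field_values(mnemonic)]
    # bound the sweep for wide fields, keeping boundary values
    ranges = [r if len(r) <= 64 else sorted(set(r[:8] + r[-8:] + r[::37]))
              for r in ranges]
    for combo in itertools.product(*ranges):
        instr = Instruction(mnemonic, dict(zip(names, combo)))
        assert decode_instruction(encode_instruction(instr)) == instr


def test_field_overflow_names_field():
    with pytest.raises(EncodeError, match="mask"):
        encode_instruction(Instruction("UPTVM", {"mask": 16}))


def test_unregistered_opcode_carries_word():
    bad = InstructionWord((0x1F << 11) | 0x123)  # 0x1F unused? POP=0x1F
    bad = InstructionWord((0x0D << 11) | 0x123)  # 0x0D is unassigned
    with pytest.raises(DecodeError) as err:
        decode_instruction(bad)
    assert err.value.word == bad.value


def test_printed_operand_fixtures_decode_to_documented_fields():
    uptwt = decode_instruction(raw_word("UPTWT", 0x108))
    assert uptwt["m"] == 0 and uptwt["nmask"] == 0b100001000
    uptls = decode_instruction(raw_word("UPTLS", 0x20))
    assert (uptls["k"], uptls["l"], uptls["m"], uptls["n"]) == (0, 1, 0, 0)
    uptvm = decode_instruction(raw_word("UPTVM", 0xD))
    assert uptvm["mask"] == 0xD
    gsprs = decode_instruction(raw_word("GSPRS", 0x0))
    assert gsprs["mask"] == 0


@pytest.mark.parametrize("name", sorted(MODEL_LISTINGS))
def test_model_listings_assemble_at_printed_length(name):
    program = assemble(MODEL_LISTINGS[name])
    assert len(program) == MODEL_LISTING_LENGTHS[name]


def test_primary_set_is_ten_opcodes():
    assert len(PRIMARY_MNEMONICS) == 10
    assert set(PRIMARY_MNEMONICS) == {
        "LSIS", "LDIP", "LSLS", "LDLP", "UPTIS", "UPTVM", "UPTLS",
        "UPTWT", "UPTTS", "GSPRS"}


def test_empty_source_gives_empty_program():
    program = assemble("")
    assert len(program) == 0
    assert disassemble(program) == ""


def test_assembler_diagnostics_carry_line_numbers():
    with pytest.raises(AssemblyError, match="line 2.*unknown mnemonic"):
        assemble("UPTVM 0xD\nBOGUS 0x1\n")
    with pytest.raises(AssemblyError, match="malformed operand"):
        assemble("UPTVM zz")
    with pytest.raises(AssemblyError, match="undefined label"):
        assemble("JMP Nowhere")
    with pytest.raises(AssemblyError, match="source operand"):
        assemble("MOV RT0, P0")  # IP0 is not source-encodable


def test_labels_resolve_case_insensitively_to_relative_offsets():
    program = assemble("JMP end\nNOP\nEnd: NOP\n")
    assert program.inference[0]["offset"] == 1


def test_sections_split_inference_and_learning():
    program = assemble(".inference\nUPTVM 0xD\n.learning\nUPTWT 0x24\n")
    assert len(program.inference) == 1 and len(program.learning) == 1


def test_disassemble_roundtrip_random_programs():
    rng = np.random.default_rng(7)
    pool = ["UPTVM", "GSPRS", "UPTLS", "UPTWT", "UPTTS", "UPTIS",
            "ADD", "SUB", "MOV", "CMP", "NOP", "LSIS", "LDLP"]
    for _ in range(50):
        instrs = []
        for _ in range(rng.integers(1, 12)):
            m = pool[rng.integers(len(pool))]
            fields = {}
            for f in instruction_fields(m):
                hi = (1 << f.width) - 1
                if f.name == "rs":
                    hi = 31
                elif f.name == "rd":
                    hi = 53  # the unified register space
                fields[f.name] = int(rng.integers(0, hi + 1))
            instrs.append(Instruction(m, fields))
        program = Program(instrs)
        assert assemble(disassemble(program)) == program


def test_binary_program_file_roundtrip():
    program = assemble(MODEL_LISTINGS["SDSP"])
    buf = io.BytesIO()
    write_program(program, buf)
    buf.seek(0)
    assert read_program(buf) == program
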