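"""Neuron-core execution: update semantics, spike stage, event handling."""

from fractions import Fraction

import numpy as np
import pytest

from darwinsim.engine import (
    EngineError,
    NeuronCore,
    WatchdogError,
    apply_tick_decay,
    exec_gsprs,
    exec_update_is,
    exec_update_ls,
    exec_update_ts,
    exec_update_vm,
    exec_update_wt,
)
from darwinsim.fixed_point import FixedPointFormat
from darwinsim.isa.asm import Program, assemble
from darwinsim.programs import MODELS, gsprs, uptvm
from darwinsim.registers import REGISTER_NAMES, RegisterFile

FMT = FixedPointFormat()


def _sat(fmt, x):
    return min(max(x, fmt.raw_min), fmt.raw_max)


def _term(fmt, p_raw, x_raw):
    """Independent rational oracle of one quantized product."""
    return _sat(fmt, (Fraction(p_raw) * Fraction(x_raw) / fmt.one).__floor__())


def _random_regs(rng, fmt=FMT, scale=2048):
    regs = RegisterFile(fmt)
    for i in range(len(regs.raw)):
        regs.raw[i] = int(rng.integers(-scale, scale))
    return regs


# -- membrane update ---------------------------------------------------------

def test_update_vm_unit_parameters():
    regs = RegisterFile(FMT, {"IP0": 1.0, "IP1": 1.0, "IC0": 0.0,
                              "S0": 5.0, "S2": 3.0})
    exec_update_vm(regs, 0b1101)
    assert regs["S0"] == 8.0


def test_update_vm_empty_mask_zeroes_membrane():
    regs = RegisterFile(FMT, {"S0": 7.0, "IC0": 3.0})
    exec_update_vm(regs, 0)
    assert regs["S0"] == 0.0


def test_update_vm_matches_rational_oracle():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        regs = _random_regs(rng)
        mask = int(rng.integers(16))
        p0, p1, p2 = (regs.get_raw(f"IP{i}") for i in range(3))
        vm, I, vadp = (regs.get_raw(s) for s in ("S0", "S2", "S4"))
        c0 = regs.get_raw("IC0")
        want = 0
        if mask & 0b1000:
            want = _sat(FMT, want + _term(FMT, p0, vm))
        if mask & 0b0100:
            want = _sat(FMT, want + _term(FMT, p1, I))
        if mask & 0b0010:
            want = _sat(FMT, want + _term(FMT, p2, vadp))
        if mask & 0b0001:
            want = _sat(FMT, want + c0)
        exec_update_vm(regs, mask)
        assert regs.get_raw("S0") == want


# -- I / g / v_adp updates ---------------------------------------------------

def test_update_is_pass_through_conductance():
    regs = RegisterFile(FMT, {"IP5": 0.0, "IP6": 1.0, "S3": 7.0})
    exec_update_is(regs, 0b010, 0b001100)
    assert regs["S1"] == 7.0


def test_update_is_masked_off_gives_zero():
    regs = RegisterFile(FMT, {"S4": 9.0, "IP3": 1.0})
    exec_update_is(regs, 0b100, 0)
    assert regs["S4"] == 0.0


def test_update_is_rejects_non_one_hot_target():
    with pytest.raises(EngineError, match="one-hot"):
        exec_update_is(RegisterFile(FMT), 0b011, 0)


def test_update_is_matches_rational_oracle():
    rng = np.random.default_rng(1)
    for _ in range(600):
        regs = _random_regs(rng)
        mask = int(rng.integers(64))
        target = (0b100, 0b010, 0b001)[int(rng.integers(3))]
        r = {n: regs.get_raw(n) for n in
             ("S0", "S1", "S3", "S4", "IP3", "IP4", "IP5", "IP6", "IP7",
              "IC1")}
        want = 0
        if target == 0b100:
            if mask & 1:
                want = _sat(FMT, want + _term(FMT, r["IP3"], r["S4"]))
            if mask & 2:
                want = _sat(FMT, want + _term(FMT, r["IP4"], r["S0"]))
            if mask & 32:
                want = _sat(FMT, want + r["IC1"])
            reg = "S4"
        elif target == 0b010:
            if mask & 4:
                want = _sat(FMT, want + _term(FMT, r["IP5"], r["S1"]))
            if mask & 8:
                want = _sat(FMT, want + _term(FMT, r["IP6"], r["S3"]))
            reg = "S1"
        else:
            if mask & 32:
                want = _sat(FMT, want + _term(FMT, r["S1"], r["S0"]))
            if mask & 16:
                want = _sat(FMT, want + _term(FMT, r["IP7"], r["S1"]))
            reg = "S2"
        exec_update_is(regs, target, mask)
        assert regs.get_raw(reg) == want


# -- learning-state updates --------------------------------------------------

def test_update_ls_constant_assignment_and_flag_gating():
    regs = RegisterFile(FMT, {"LP1": 0.0, "LC2": 1.5, "LS4": 9.0})
    exec_update_ls(regs, 4, 1, 4, 2)
    assert regs["LS4"] == 1.5
    regs = RegisterFile(FMT, {"LP2": 0.75, "LS2": 1.0, "LC0": 0.0})
    exec_update_ls(regs, 0, 2, 2, 0)
    assert regs["LS0"] == 0.75


def test_update_ls_geometric_decay_closed_form():
    lam = 0.875
    regs = RegisterFile(FMT, {"LP0": lam, "LS3": 100.0, "LC0": 0.0})
    for t in range(1, 40):
        exec_update_ls(regs, 3, 0, 3, 0)
        closed = 100.0 * lam ** t
        assert abs(regs["LS3"] - closed) <= t / 256  # quantization drift


def test_update_ls_field_range_checked():
    with pytest.raises(EngineError):
        exec_update_ls(RegisterFile(FMT), 10, 0, 0, 0)


def test_update_wt_gating_and_identity_product():
    regs = RegisterFile(FMT, {"LP0": 1.0, "LS0": 2.5, "LS5": 0.0, "W": 1.0})
    exec_update_wt(regs, 0, 0b000100001)   # includes the zero flag LS5
    assert regs["W"] == 1.0
    exec_update_wt(regs, 0, 0b000000001)   # only LS0
    assert regs["W"] == 3.5
    exec_update_wt(regs, 0, 0)             # empty selection: unchanged
    assert regs["W"] == 3.5


def test_update_ts_constant_when_multiplier_zero():
    regs = RegisterFile(FMT, {"IP2": 0.0, "IC1": 2.25, "S3": 9.0})
    exec_update_ts(regs, 6, 2, 3, 1)
    assert regs["TR6"] == 2.25


# -- spike stage -------------------------------------------------------------

def test_gsprs_rule_exhaustive_small_grid():
    vth = FMT.quantize(1.0)
    for vm_raw in range(-3 * 256, 3 * 256 + 1, 64):
        for mask in range(16):
            regs = RegisterFile(FMT, {"V0": -0.5, "IC2": 0.25, "S4": 1.0})
            regs.set_raw("S0", vm_raw)
            regs.set_raw("S5", vth)
            spike = exec_gsprs(regs, mask)
            compare = bool(mask & 0b0100)
            above = vm_raw > vth
            # brute-force enumeration of the rule
            if not (compare and above):
                assert not spike
                assert regs.get_raw("S0") == vm_raw
                assert regs["S4"] == 1.0
            else:
                assert spike == bool(mask & 0b1000)
                if mask & 0b0001:
                    assert regs["S0"] == -0.5
                else:
                    assert regs.get_raw("S0") == vm_raw
                assert regs["S4"] == (1.25 if mask & 0b0010 else 1.0)


def test_gsprs_equal_threshold_does_not_fire():
    regs = RegisterFile(FMT, {"S0": 1.0, "S5": 1.0, "V0": 0.0})
    assert exec_gsprs(regs, 0b1111) is False
    assert regs["S0"] == 1.0


# -- input accumulation ------------------------------------------------------

def test_tick_decay_cases():
    regs = RegisterFile(FMT, {"IP8": 0.0, "S3": 3.0})
    apply_tick_decay(regs, FMT.quantize(2.0))
    assert regs["S3"] == 2.0          # p8 = 0: buffer only
    regs = RegisterFile(FMT, {"IP8": 1.0, "S3": 3.0})
    apply_tick_decay(regs, 0)
    assert regs["S3"] == 3.0          # p8 = 1, no input: unchanged


def test_accumulate_input_is_additive():
    spec = MODELS["cuba_delta"]
    core = NeuronCore(4, spec.program, FMT)
    core.init_registers(spec.registers)
    core.accumulate_input(1, FMT.quantize(3.0))
    core.accumulate_input(1, FMT.quantize(-1.0))
    core.step()
    # h held the folded sum before the delta chain consumed it into I
    assert core.registers[1]["S2"] == 2.0
    with pytest.raises(EngineError, match="neuron 9"):
        core.accumulate_input(9, 1)


# -- program execution -------------------------------------------------------

def test_gsprs_only_program_is_state_invariant():
    program = Program([gsprs(0)])
    core = NeuronCore(2, program, FMT)
    core.init_registers({"S0": 1.0, "S5": 0.0, "IP8": 1.0})
    before = [list(r.raw) for r in core.registers]
    for _ in range(20):
        assert core.step() == []
    assert [list(r.raw) for r in core.registers] == before


def test_extended_ops_and_mov_alias():
    program = Program(assemble("MOV P0, RT0\nADD S0, TR1\n").inference)
    core = NeuronCore(1, program, FMT)
    core.init_registers({"TR0": 1.25, "TR1": 0.0, "S0": 2.0})
    core.run_program(0)
    assert core.registers[0]["IP0"] == 1.25
    assert core.registers[0]["S0"] == 2.0  # ADD with zero is identity


def test_watchdog_catches_unbounded_jump_loop():
    program = Program(assemble("Loop: JMP Loop\n").inference)
    core = NeuronCore(1, program, FMT)
    with pytest.raises(WatchdogError, match="neuron 0"):
        core.run_program(0)


def test_memory_fault_identifies_neuron_and_address():
    program = Program(assemble("SUB TR0, TR0\nADDI TR0, -5\nSA TR0\nLOAD TR1\n").inference)
    core = NeuronCore(1, program, FMT)
    with pytest.raises(EngineError, match="address -5"):
        core.run_program(0)


def test_core_determinism_identical_trajectories():
    spec = MODELS["adlif"]
    runs = []
    for _ in range(2):
        core = NeuronCore(3, spec.program, FMT)
        core.init_registers(spec.registers)
        rng = np.random.default_rng(5)
        trace = []
        for _ in range(200):
            n = int(rng.integers(3))
            core.accumulate_input(n, FMT.quantize(0.5))
            trace.append((tuple(core.step()),
                          tuple(core.registers[0].raw)))
        runs.append(trace)
    assert runs[0] == runs[1]


def test_saturation_invariant_under_random_execution():
    spec = MODELS["izhikevich"]
    core = NeuronCore(1, spec.program, spec.fmt)
    core.init_registers(spec.registers)
    rng = np.random.default_rng(9)
    for _ in range(300):
        core.accumulate_input(0, int(rng.integers(-2 ** 14, 2 ** 14)))
        core.step()
        core.registers[0].assert_in_range()


def test_spike_flags_last_exactly_one_step():
    spec = MODELS["stdp_basic"]
    core = NeuronCore(1, spec.program, FMT, mode="both")
    core.init_registers(spec.registers)
    syn = core.add_synapse("pre", 0, 0)
    core.deliver_spike("pre", 0)
    assert syn.ls[2] == FMT.one          # raised at delivery
    core.accumulate_input(0, FMT.quantize(8.0))
    fired = core.step()
    assert fired == [0]
    assert syn.ls[2] == 0 and syn.ls[5] == 0   # cleared after learning
    core.step()
    assert syn.ls[2] == 0 and syn.ls[5] == 0


def test_core_construction_limits():
    program = Program([uptvm(0)])
    with pytest.raises(EngineError, match="4096"):
        NeuronCore(4097, program, FMT)
    with pytest.raises(EngineError, match="learning section"):
        NeuronCore(1, Program([uptvm(0)]), FMT, mode="both")


def test_register_dump_covers_all_registers():
    core = NeuronCore(2, Program([uptvm(0)]), FMT)
    dump = core.dump_registers()
    assert len(dump) == 2
    assert set(dump[0]) == set(REGISTER_NAMES)
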