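"""Whole-chip runtime: configuration, ticks, determinism, capacity."""

import math

import pytest

from darwinsim.chip import (
    Chip,
    ChipConfig,
    ConfigError,
    NeuronCoreConfig,
    capacity_report,
    load_config,
    save_config,
    spikes_to_frame,
)
from darwinsim.connectivity import CapacityError, ConnectionList, Edge
from darwinsim.isa.asm import Program
from darwinsim.programs import MODELS, gsprs, uptvm

A, B = (1, 0), (2, 0)


def _lif_core(coord, neurons=4, mode="inference", **regs):
    spec = MODELS["cuba_delta"]
    base = dict(spec.registers)
    base.update(regs)
    program = spec.program
    if mode == "both":
        program = Program(list(program.inference),
                          list(MODELS["stdp_basic"].program.learning))
        base.update({k: v for k, v in MODELS["stdp_basic"].registers.items()
                     if k.startswith(("LP", "LC", "TR"))})
    return NeuronCoreConfig(coord=coord, neuron_count=neurons,
                            program=program, mode=mode, registers=base)


def _two_core_config(weight=2048):
    conns = ConnectionList([Edge(A, 0, B, 1, weight, 16)])
    return ChipConfig(mesh_dims=(4, 4),
                      cores=[_lif_core(A), _lif_core(B)],
                      connections=conns,
                      stimuli=[(1, A, 0, 8.0)])


# -- validation --------------------------------------------------------------

def test_management_node_cannot_host_a_core():
    cfg = ChipConfig(cores=[_lif_core((0, 0))])
    with pytest.raises(ConfigError, match="management"):
        cfg.validate()


def test_neuron_count_ceiling_enforced():
    with pytest.raises(ConfigError, match="4096"):
        ChipConfig(cores=[_lif_core(A, neurons=4097)]).validate()


def test_connection_to_unconfigured_core_rejected():
    cfg = _two_core_config()
    cfg.connections = ConnectionList([Edge(A, 0, (3, 3), 0, 1, 16)])
    with pytest.raises(ConfigError, match="not configured"):
        cfg.validate()


def test_capacity_error_names_offending_core():
    cfg = _two_core_config()
    cfg.cores[1].d2 = cfg.cores[1].neuron_count  # zero fan-out budget
    cfg.cores[1].d1 = 2
    big = [Edge(B, 0, A, t, 1, 16) for t in range(4)]
    big += [Edge(B, 1, A, t, 1, 16) for t in range(4)]
    big += [Edge(B, 2, A, t, 1, 16) for t in range(4)]
    cfg.connections = ConnectionList(big)
    with pytest.raises(CapacityError, match=r"\(2, 0\)"):
        Chip(cfg)


# -- dynamics ----------------------------------------------------------------

def test_silent_chip_emits_nothing_and_keeps_state():
    cfg = _two_core_config()
    cfg.stimuli = []
    chip = Chip(cfg)
    before = [list(r.raw) for c in chip.cores.values() for r in c.registers]
    assert chip.run(20) == []
    after = [list(r.raw) for c in chip.cores.values() for r in c.registers]
    assert before == after


def test_two_core_spike_arrives_next_step():
    chip = Chip(_two_core_config())
    rec1 = chip.tick()
    assert [(r.core, r.neuron) for r in rec1] == [(A, 0)]   # source fires
    rec2 = chip.tick()
    # the delivered weight (8.0 = 2048 raw) drives B past its threshold
    assert [(r.core, r.neuron) for r in rec2] == [(B, 1)]
    assert rec2[0].step == 2


def test_idle_core_purity_with_traffic_elsewhere():
    cfg = _two_core_config()
    idle = _lif_core((3, 3))
    cfg.cores.append(idle)
    chip = Chip(cfg)
    before = [list(r.raw) for r in chip.cores[(3, 3)].registers]
    chip.run(10)
    assert [list(r.raw) for r in chip.cores[(3, 3)].registers] == before


def test_periodic_bias_neuron_matches_closed_form():
    """A delta neuron with constant drive q and p0 = 1 integrates
    v(t) = t*q and fires with period floor(vth/q) + 1."""
    spec = MODELS["cuba_delta"]
    regs = dict(spec.registers, IP0=1.0, S5=4.0, V0=0.0)
    core = NeuronCoreConfig(coord=A, neuron_count=1, program=spec.program,
                            registers=regs)
    q = 1.5
    cfg = ChipConfig(mesh_dims=(4, 4), cores=[core],
                     stimuli=[(t, A, 0, q) for t in range(1, 41)])
    chip = Chip(cfg)
    records = chip.run(40)
    period = math.floor(4.0 / q) + 1
    want = list(range(period, 41, period))
    assert [r.step for r in records] == want


def test_run_zero_steps_and_determinism():
    assert Chip(_two_core_config()).run(0) == []
    r1 = Chip(_two_core_config()).run(30)
    r2 = Chip(_two_core_config()).run(30)
    assert r1 == r2


def test_spike_conservation_end_to_end():
    """Every fired spike produces exactly its fan-out in synaptic events."""
    conns = ConnectionList([Edge(A, 0, B, t, 256, 16) for t in range(4)])
    cfg = ChipConfig(mesh_dims=(4, 4),
                     cores=[_lif_core(A), _lif_core(B, S5=100.0)],
                     connections=conns, stimuli=[(1, A, 0, 8.0)])
    chip = Chip(cfg)
    chip.tick()                      # A0 fires
    chip.tick()                      # 4 events land in B
    # every B neuron integrated exactly one weight-1.0 event
    assert [chip.cores[B].registers[t]["S0"] for t in range(4)] == [1.0] * 4


def test_learning_weights_update_through_runtime():
    cfg = _two_core_config()
    cfg.cores[1] = _lif_core(B, mode="both")
    # potentiation only: a causal pre->post pair must strengthen
    cfg.cores[1].registers["LP1"] = 0.0
    chip = Chip(cfg)
    w0 = chip.learned_weight((A, 0), (B, 1))
    chip.run(3)   # A0 fires at 1, B1 fires at 2: causal pair strengthens
    assert chip.learned_weight((A, 0), (B, 1)) > w0


def test_spike_frame_export():
    chip = Chip(_two_core_config())
    frame = spikes_to_frame(chip.run(3))
    assert list(frame.columns) == ["step", "core_x", "core_y", "neuron"]
    assert len(frame) == 2


# -- capacity reporting ------------------------------------------------------

def test_default_geometry_capacity_totals():
    rep = capacity_report()
    assert rep.neuron_cores == 575
    assert rep.total_neurons == 2_355_200
    assert rep.total_neurons_millions == 2.36  # reported as ~2.35 million
    assert rep.total_neurons >= 2.35e6


def test_small_mesh_capacity():
    rep = capacity_report((2, 2))
    assert rep.neuron_cores == 3
    assert rep.total_neurons == 12_288


# -- configuration files -----------------------------------------------------

def test_config_save_load_roundtrip(tmp_path):
    cfg = _two_core_config()
    cfg.cores[1] = _lif_core(B, mode="both")
    cfg.cores[1].neuron_registers = {2: {"S5": 9.0}}
    path = tmp_path / "chip.yaml"
    save_config(cfg, path)
    loaded = load_config(path)
    assert loaded.mesh_dims == cfg.mesh_dims
    assert loaded.connections == cfg.connections
    assert loaded.stimuli == cfg.stimuli
    for a, b in zip(loaded.cores, cfg.cores):
        assert a.program == b.program
        assert a.registers == b.registers
        assert a.neuron_registers == b.neuron_registers
        assert (a.coord, a.neuron_count, a.mode) == \
            (b.coord, b.neuron_count, b.mode)
    # loaded config actually runs identically
    assert Chip(loaded).run(10) == Chip(cfg).run(10)


def test_minimal_config_loads_from_text(tmp_path):
    text = """
mesh: [4, 4]
cores:
  - coord: [1, 0]
    neurons: 1
    program: |
      UPTIS 0x88
      UPTIS 0x50
      UPTVM 0xC
      GSPRS 0xD
    registers: {IP0: 1.0, IP1: 1.0, IP6: 1.0, IP7: 1.0, S5: 2.0}
stimuli: [[1, 1, 0, 0, 8.0]]
"""
    path = tmp_path / "min.yaml"
    path.write_text(text)
    chip = Chip(load_config(path))
    records = chip.run(2)
    assert [(r.step, r.neuron) for r in records] == [(1, 0)]


def test_malformed_config_diagnostics(tmp_path):
    path = tmp_path / "bad.yaml"
    path.write_text("cores:\n  - coord: [1, 0]\n    neurons: nope\n")
    with pytest.raises(ConfigError, match=r"core \[1, 0\]"):
        load_config(path)
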