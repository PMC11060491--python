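"""Executable ISA programs for the supported model family.

Each entry pairs an assembled :class:`~darwinsim.isa.asm.Program` (and the
register values it expects) with the reference stepper from
:mod:`darwinsim.models` that computes the same discrete update directly.
The bit-exact agreement of the two is the central verification surface
of the simulator (see :mod:`darwinsim.verify`).

Conventions used by the neuron programs:

* spike input accumulates into the gating variable ``h`` each step
  (``h <- p8 h + input``); a delta synapse sets ``p8 = 0`` so ``h`` is
  the per-step weighted spike sum, and routes it to the current via
  ``g = p6 h`` (p6 = 1), ``I = p7 g`` (p7 = 1);
* learning programs run per synapse with the trace registers LS0..LS9
  and the weight W overlaid from the synapse record; trace increments
  are flag-gated products built from MOV/MUL/ADD with the increment
  amplitudes held in temporaries TR4..TR7.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Dict, Optional

from .fixed_point import FixedPointFormat
from .isa.asm import Program, assemble
from .isa.instructions import Instruction
from . import models


def ins(text: str) -> Instruction:
    """Assemble a single instruction from source text."""
    return assemble(text).inference[0]


# mask helpers --------------------------------------------------------------

UPTVM_VM = 0b1000
UPTVM_I = 0b0100
UPTVM_VADP = 0b0010
UPTVM_C0 = 0b0001

UPTIS_P3 = 0b000001
UPTIS_P4 = 0b000010
UPTIS_P5 = 0b000100
UPTIS_P6 = 0b001000
UPTIS_P7 = 0b010000
UPTIS_C1_GV = 0b100000

GSPRS_FIRE = 0b1000
GSPRS_CMP = 0b0100
GSPRS_ADAPT = 0b0010
GSPRS_RESET = 0b0001


def uptvm(mask: int) -> Instruction:
    return Instruction("UPTVM", {"mask": mask})


def uptis(target: int, mask: int) -> Instruction:
    return Instruction("UPTIS", {"target": target, "mask": mask})


def uptls(k: int, l: int, m: int, n: int) -> Instruction:
    return Instruction("UPTLS", {"k": k, "l": l, "m": m, "n": n})


def uptts(k: int, l: int, m: int, n: int) -> Instruction:
    return Instruction("UPTTS", {"k": k, "l": l, "m": m, "n": n})


def uptwt(m: int, nmask: int) -> Instruction:
    return Instruction("UPTWT", {"m": m, "nmask": nmask})


def gsprs(mask: int) -> Instruction:
    return Instruction("GSPRS", {"mask": mask})


def lif_membrane_update() -> Instruction:
    """The LIF membrane update v <- p0 v + p1 I + c0 (2 mul, 2 add)."""
    return uptvm(UPTVM_VM | UPTVM_I | UPTVM_C0)


def cuba_delta_membrane_update() -> Instruction:
    """The delta-synapse membrane update v <- p0 v + I (1 mul, 1 add
    when p1 is held at exactly 1)."""
    return uptvm(UPTVM_VM | UPTVM_I)


# delta-synapse input chain: g = h, I = g
_DELTA_CHAIN = [uptis(0b010, UPTIS_P6), uptis(0b001, UPTIS_P7)]
# dual-exponential conductance chain: g = p5 g + p6 h
_DUALEXP_G = uptis(0b010, UPTIS_P5 | UPTIS_P6)

# flag-gated trace increment: LS_target += amp_reg * LS_flag
def _trace_inc(target_ls: int, flag_ls: int, amp_tr: str) -> list:
    return [ins(f"MOV LS9, LS{flag_ls}"),
            ins(f"MUL LS9, {amp_tr}"),
            ins(f"ADD LS{target_ls}, LS9")]


# ---------------------------------------------------------------------------
# Model registry
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """A model program plus everything needed to run and verify it."""

    name: str
    kind: str                       # "neuron" | "learning"
    program: Program
    registers: Dict[str, float]     # register init (per neuron)
    reference: Callable             # fmt, params[, state] -> stepper
    ref_params: Dict[str, float]
    fmt: FixedPointFormat = dc_field(default_factory=FixedPointFormat)
    state_init: Dict[str, float] = dc_field(default_factory=dict)
    ls_init: Dict[int, float] = dc_field(default_factory=dict)
    input_amplitude: float = 1.0    # weight of one input spike (neuron kind)
    input_rate: float = 0.3         # Bernoulli rate of the test spike train


def _post_driver(reset: bool = True) -> list:
    """Inference section of the learning test neuron: v_m equals the
    accumulated input each step (p1 = p6 = p7 = 1, p8 = 0)."""
    mask = GSPRS_FIRE | GSPRS_CMP | (GSPRS_RESET if reset else 0)
    return [*_DELTA_CHAIN, uptvm(UPTVM_I), gsprs(mask)]


_POST_DRIVER_REGS = {"IP1": 1.0, "IP6": 1.0, "IP7": 1.0, "IP8": 0.0,
                     "S5": 4.0, "V0": 0.0}


def _lif_spec() -> ModelSpec:
    regs = {"IP0": 0.9, "IP1": 0.125, "IC0": 0.05, "IP5": 0.75,
            "IP6": 1.0, "IP7": 1.0, "IP8": 0.5, "S5": 6.0, "V0": 0.0}
    program = Program([
        _DUALEXP_G,
        uptis(0b001, UPTIS_P7),
        uptvm(UPTVM_VM | UPTVM_I | UPTVM_C0),
        gsprs(GSPRS_FIRE | GSPRS_CMP | GSPRS_RESET),
    ])
    ref = {"p0": 0.9, "p1": 0.125, "c0": 0.05, "p5": 0.75, "p6": 1.0,
           "p7": 1.0, "p8": 0.5, "vth": 6.0, "v0": 0.0}
    return ModelSpec("lif", "neuron", program, regs, models.RefLIF, ref,
                     input_amplitude=2.0)


def _coba_spec() -> ModelSpec:
    regs = {"IP0": 0.9, "IP1": 0.0625, "IC0": 0.05, "IP5": 0.75,
            "IP6": 1.0, "IP7": 0.25, "IP8": 0.5, "S5": 8.0, "V0": 0.0}
    program = Program([
        _DUALEXP_G,
        uptis(0b001, UPTIS_C1_GV | UPTIS_P7),
        uptvm(UPTVM_VM | UPTVM_I | UPTVM_C0),
        gsprs(GSPRS_FIRE | GSPRS_CMP | GSPRS_RESET),
    ])
    ref = {"p0": 0.9, "p1": 0.0625, "c0": 0.05, "p5": 0.75, "p6": 1.0,
           "p7": 0.25, "p8": 0.5, "vth": 8.0, "v0": 0.0}
    return ModelSpec("coba", "neuron", program, regs, models.RefCOBA, ref,
                     input_amplitude=0.5)


def _adlif_spec() -> ModelSpec:
    regs = {"IP0": 0.9, "IP1": 0.0625, "IP2": -0.0625, "IC0": 0.05,
            "IP3": 0.9375, "IP4": 0.0625, "IC1": 0.0, "IC2": 0.5,
            "IP5": 0.75, "IP6": 1.0, "IP7": 0.25, "IP8": 0.5,
            "S5": 6.0, "V0": 0.0}
    program = Program([
        _DUALEXP_G,
        uptis(0b001, UPTIS_C1_GV | UPTIS_P7),
        uptis(0b100, UPTIS_P3 | UPTIS_P4 | UPTIS_C1_GV),
        uptvm(0b1111),
        gsprs(0b1111),
    ])
    ref = {"p0": 0.9, "p1": 0.0625, "p2": -0.0625, "c0": 0.05,
           "p3": 0.9375, "p4": 0.0625, "c1": 0.0, "c2": 0.5,
           "p5": 0.75, "p6": 1.0, "p7": 0.25, "p8": 0.5,
           "vth": 6.0, "v0": 0.0}
    return ModelSpec("adlif", "neuron", program, regs, models.RefAdLIF, ref,
                     input_amplitude=0.5)


def _cuba_delta_spec() -> ModelSpec:
    regs = {"IP0": 0.875, "IP1": 1.0, "IP6": 1.0, "IP7": 1.0, "IP8": 0.0,
            "S5": 4.0, "V0": 0.0}
    program = Program([
        *_DELTA_CHAIN,
        cuba_delta_membrane_update(),
        gsprs(GSPRS_FIRE | GSPRS_CMP | GSPRS_RESET),
    ])
    ref = {"p0": 0.875, "p1": 1.0, "p6": 1.0, "p7": 1.0, "p8": 0.0,
           "vth": 4.0, "v0": 0.0}
    return ModelSpec("cuba_delta", "neuron", program, regs,
                     models.RefCUBADelta, ref, input_amplitude=1.5)


def _qif_spec() -> ModelSpec:
    regs = {"IP1": 0.05, "IC1": 0.75, "IC0": 0.5, "IP6": 1.0, "IP7": 1.0,
            "IP8": 0.0, "S5": 10.0, "V0": 0.0}
    program = Program([
        *_DELTA_CHAIN,
        uptts(0, 1, 0, 1),            # RT0 = p1 v_m + c1
        ins("MOV P0, RT0"),
        uptvm(UPTVM_VM | UPTVM_I | UPTVM_C0),
        gsprs(GSPRS_FIRE | GSPRS_CMP | GSPRS_RESET),
    ])
    ref = {"p1": 0.05, "c1": 0.75, "c0": 0.5, "p6": 1.0, "p7": 1.0,
           "p8": 0.0, "vth": 10.0, "v0": 0.0}
    return ModelSpec("qif", "neuron", program, regs, models.RefQIF, ref,
                     input_amplitude=1.0)


def _expif_spec() -> ModelSpec:
    regs = {"IP0": 0.9, "IP1": 0.125, "IP3": 0.5, "IC1": -2.0,
            "TR2": 0.5, "TR3": 0.25, "IP6": 1.0, "IP7": 1.0, "IP8": 0.0,
            "S5": 4.0, "V0": 0.0}
    program = Program([
        uptts(0, 3, 0, 1),            # RT0 = p3 v_m + c1 in [-8, 0]
        ins("EXP RT1, RT0"),
        ins("MUL RT1, RT2"),
        ins("ADD RT1, RT3"),
        ins("MOV C0, RT1"),
        *_DELTA_CHAIN,
        uptvm(UPTVM_VM | UPTVM_I | UPTVM_C0),
        gsprs(GSPRS_FIRE | GSPRS_CMP | GSPRS_RESET),
    ])
    ref = {"p0": 0.9, "p1": 0.125, "p3": 0.5, "c1": -2.0,
           "exp_scale": 0.5, "exp_offset": 0.25, "p6": 1.0, "p7": 1.0,
           "p8": 0.0, "vth": 4.0, "v0": 0.0}
    return ModelSpec("expif", "neuron", program, regs, models.RefExpIF, ref,
                     input_amplitude=0.5)


def _izhikevich_spec() -> ModelSpec:
    fmt = FixedPointFormat(total_bits=24, fraction_bits=12)
    regs = {"IP5": 0.02, "IC1": 3.5, "IP1": 0.5, "IP2": -0.5, "IC0": 70.0,
            "IP3": 0.99, "IP4": 0.002, "IC2": 8.0, "IP6": 1.0, "IP7": 1.0,
            "IP8": 0.0, "S5": 30.0, "V0": -65.0, "S0": -65.0, "S4": -13.0}
    program = Program([
        *_DELTA_CHAIN,
        uptts(0, 5, 0, 1),            # RT0 = pquad v_m + c1
        ins("MOV P0, RT0"),
        uptis(0b100, UPTIS_P3 | UPTIS_P4),
        uptvm(0b1111),
        gsprs(0b1111),
    ])
    ref = {"pquad": 0.02, "c1": 3.5, "p1": 0.5, "p2": -0.5, "c0": 70.0,
           "p3": 0.99, "p4": 0.002, "c2": 8.0, "p6": 1.0, "p7": 1.0,
           "p8": 0.0, "vth": 30.0, "v0": -65.0}
    return ModelSpec("izhikevich", "neuron", program, regs,
                     models.RefIzhikevich, ref, fmt=fmt,
                     state_init={"vm": -65.0, "vadp": -13.0},
                     input_amplitude=4.0)


# -- learning models --------------------------------------------------------

_PAIR_TRACES = [
    uptls(0, 3, 0, 0),                # x0 *= P3* (LC0 = 0)
    *_trace_inc(0, 2, "TR4"),         # x0 += a_pre * x2
    uptls(3, 4, 3, 0),                # y0 *= P4*
    *_trace_inc(3, 5, "TR5"),         # y0 += a_post0 * y2
]
_Y1_TRACE = [
    uptls(4, 5, 4, 0),                # y1 *= P5*
    *_trace_inc(4, 5, "TR6"),         # y1 += a_post1 * y2
]
_R_TRACE = [
    uptls(6, 6, 6, 0),                # r0 *= P6*
    *_trace_inc(6, 8, "TR7"),         # r0 += a_rwd * r2
]

_STDP_COMMON_REGS = {
    **_POST_DRIVER_REGS,
    "LP3": 0.875, "TR4": 0.5,         # x0 decay / increment
    "LP4": 0.875, "TR5": 0.5,         # y0 decay / increment
    "LC0": 0.0,
}
_STDP_COMMON_REF = {"Px": 0.875, "ax": 0.5, "Py0": 0.875, "ay0": 0.5,
                    "vth": 4.0}


def _stdp_basic_spec() -> ModelSpec:
    regs = {**_STDP_COMMON_REGS, "LP0": 0.0625, "LP1": -0.0625}
    program = Program(_post_driver(), [
        *_PAIR_TRACES,
        uptwt(0, 0b000100001),        # += A0 x0 y2
        uptwt(1, 0b000001100),        # += A1 x2 y0
    ])
    ref = {**_STDP_COMMON_REF, "A0": 0.0625, "A1": -0.0625}
    return ModelSpec("stdp_basic", "learning", program, regs,
                     models.RefPairSTDP, ref)


def _stdp_triplet_spec() -> ModelSpec:
    regs = {**_STDP_COMMON_REGS, "LP0": 0.0625, "LP1": -0.0625,
            "LP2": -0.03125, "LP5": 0.9375, "TR6": 0.25,
            "LP6": 1.0, "TR7": 0.0}
    program = Program(_post_driver(), [
        *_PAIR_TRACES,
        *_Y1_TRACE,
        *_R_TRACE,                    # P6* = 1, a = 0: r0 stays at 1
        uptwt(0, 0b001100001),        # += A0 x0 y2 r0
        uptwt(1, 0b001001100),        # += A1 x2 y0 r0
        uptwt(2, 0b001010100),        # += A2 x2 y1 r0
    ])
    ref = {**_STDP_COMMON_REF, "A0": 0.0625, "A1": -0.0625, "A2": -0.03125,
           "Py1": 0.9375, "ay1": 0.25, "Pr": 1.0, "ar": 0.0, "r0_init": 1.0}
    return ModelSpec("stdp_triplet", "learning", program, regs,
                     models.RefTripletSTDP, ref, ls_init={6: 1.0})


def _rstdp_spec() -> ModelSpec:
    regs = {**_STDP_COMMON_REGS, "LP0": 0.0625, "LP1": -0.0625,
            "LP6": 0.9375, "TR7": 0.5}
    program = Program(_post_driver(), [
        *_PAIR_TRACES,
        *_R_TRACE,
        uptwt(0, 0b001100001),        # += A0 x0 y2 r0
        uptwt(1, 0b001001100),        # += A1 x2 y0 r0
    ])
    ref = {**_STDP_COMMON_REF, "A0": 0.0625, "A1": -0.0625,
           "Pr": 0.9375, "ar": 0.5, "r0_init": 0.0}
    return ModelSpec("rstdp", "learning", program, regs, models.RefRSTDP, ref)


def _sdsp_spec() -> ModelSpec:
    regs = {**_POST_DRIVER_REGS,
            "LP4": 0.9375, "TR5": 0.5,   # calcium decay / increment
            "TR0": 2.0,                  # depolarisation threshold
            "TR1": 0.25,                 # calcium lower bound
            "TR3": 3.0,                  # calcium upper bound
            "TR2": 1.5,                  # potentiate/depress split
            "TR4": 0.0625,               # weight step
            "LC0": 0.0}
    learning = [
        uptls(1, 4, 1, 0),               # calcium trace in LS1
        *_trace_inc(1, 5, "TR5"),
        *assemble(
            "CMP RT0 S0\n"
            "JMP Keep\n"
            "CMP RT1 LS1\n"
            "JMP Keep\n"
            "CMP LS1 RT3\n"
            "JMP Keep\n"
            "CMP LS1 RT2\n"
            "JMP Up\n"
            "SUB W RT4\n"
            "JMP Done\n"
            "Up: ADD W RT4\n"
            "Keep: NOP\n"
            "Done: NOP\n").inference,
    ]
    program = Program(_post_driver(reset=False), learning)
    ref = {"Pc": 0.9375, "ac": 0.5, "thr_v": 2.0, "thr_lo": 0.25,
           "thr_hi": 3.0, "thr_split": 1.5, "step": 0.0625, "vth": 4.0}
    return ModelSpec("sdsp", "learning", program, regs, models.RefSDSP, ref)


def _stp_hidden_spec() -> ModelSpec:
    regs = {**_POST_DRIVER_REGS, "IP0": 0.25, "IC0": 0.125, "S5": 8.0}
    program = Program(_post_driver(reset=False), [
        uptts(0, 0, 0, 0),            # RT0 = p0 v_m + c0
        ins("MOV LP0, RT0"),
        uptwt(0, 0b011000000),        # += rate r0 r1
    ])
    ref = {"p0": 0.25, "c0": 0.125, "vth": 8.0}
    return ModelSpec("stp_hidden", "learning", program, regs,
                     models.RefSTPHidden, ref,
                     ls_init={6: 0.5, 7: 0.25})


def _build_registry() -> Dict[str, ModelSpec]:
    specs = [
        _lif_spec(), _coba_spec(), _adlif_spec(), _cuba_delta_spec(),
        _qif_spec(), _expif_spec(), _izhikevich_spec(),
        _stdp_basic_spec(), _stdp_triplet_spec(), _rstdp_spec(),
        _sdsp_spec(), _stp_hidden_spec(),
    ]
    return {s.name: s for s in specs}


MODELS: Dict[str, ModelSpec] = _build_registry()
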