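"""Register file of one logical neuron.

The architecture exposes a flat set of named registers per logical neuron:

* ``S0..S5``  — inference state: membrane potential v_m, conductance g,
  synaptic current I, gating variable h, adaptive voltage v_adp,
  threshold v_th;
* ``W``       — the synaptic weight of the synapse currently being
  processed (per-synapse, overlaid during learning);
* ``V0``      — the reset membrane potential;
* ``IP0..IP8``— inference multipliers p0..p8 (p8 is the gating-variable
  decay; see the methods note for why a ninth slot exists);
* ``IC0..IC2``— inference constants c0..c2;
* ``LS0..LS9``— learning state: pre traces x0,x1, pre-spike flag x2,
  post traces y0,y1, post-spike flag y2, reward traces r0,r1, reward
  input r2, and one scratch trace;
* ``LP0..LP7``— learning multipliers P0*..P6* (+1 spare);
* ``LC0..LC7``— learning constants C0*..C3* (+4 spare);
* ``TR0..TR7``— temporaries (also addressed as RT0..RT7).

The unified index order below doubles as the register encoding used by
the extended instructions: indices 0..31 can be encoded as a *source*
operand (5 bits), all 54 as a *destination* (6 bits).  Registers that are
plausibly read by extended instructions therefore occupy the low half.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Dict, Iterable, Mapping

from .fixed_point import FixedPointFormat

# ---------------------------------------------------------------------------
# Unified register index space
# ---------------------------------------------------------------------------

REGISTER_NAMES = (
    [f"TR{i}" for i in range(8)]        # 0..7
    + [f"S{i}" for i in range(6)]       # 8..13
    + [f"LS{i}" for i in range(10)]     # 14..23
    + ["W"]                             # 24
    + [f"LC{i}" for i in range(4)]      # 25..28  (sources for trace updates)
    + [f"IC{i}" for i in range(3)]      # 29..31
    + ["V0"]                            # 32
    + [f"LC{i}" for i in range(4, 8)]   # 33..36
    + [f"IP{i}" for i in range(9)]      # 37..45
    + [f"LP{i}" for i in range(8)]      # 46..53
)

NUM_REGISTERS = len(REGISTER_NAMES)
REG_INDEX: Dict[str, int] = {name: i for i, name in enumerate(REGISTER_NAMES)}

# Mnemonic aliases used in assembly listings.
REGISTER_ALIASES: Dict[str, str] = {
    **{f"RT{i}": f"TR{i}" for i in range(8)},
    **{f"P{i}": f"IP{i}" for i in range(9)},
    **{f"C{i}": f"IC{i}" for i in range(3)},
    "X0": "LS0", "X1": "LS1", "X2": "LS2",
    "Y0": "LS3", "Y1": "LS4", "Y2": "LS5",
    "R0": "LS6", "R1": "LS7", "R2": "LS8",
    "VM": "S0", "VTH": "S5",
}

MAX_SOURCE_INDEX = 31  # extended-op source field is 5 bits wide

# Handy group index lists
TR = [REG_INDEX[f"TR{i}"] for i in range(8)]
S = [REG_INDEX[f"S{i}"] for i in range(6)]
LS = [REG_INDEX[f"LS{i}"] for i in range(10)]
IP = [REG_INDEX[f"IP{i}"] for i in range(9)]
IC = [REG_INDEX[f"IC{i}"] for i in range(3)]
LP = [REG_INDEX[f"LP{i}"] for i in range(8)]
LC = [REG_INDEX[f"LC{i}"] for i in range(8)]
W = REG_INDEX["W"]
V0 = REG_INDEX["V0"]


def resolve_register(name: str) -> int:
    """Map an assembly register name (or alias) to its unified index."""
    key = name.upper().rstrip(",")
    key = REGISTER_ALIASES.get(key, key)
    if key not in REG_INDEX:
        raise KeyError(f"unknown register {name!r}")
    return REG_INDEX[key]


class RegisterFile:
    """All named registers of one logical neuron, stored as raw fixed point."""

    __slots__ = ("fmt", "raw")

    def __init__(self, fmt: FixedPointFormat | None = None,
                 init: Mapping[str, float] | None = None) -> None:
        self.fmt = fmt or FixedPointFormat()
        self.raw = [0] * NUM_REGISTERS
        if init:
            for name, value in init.items():
                self[name] = value

    # raw access by unified index ----------------------------------------
    def get(self, index: int) -> int:
        return self.raw[index]

    def set(self, index: int, raw: int) -> None:
        if not self.fmt.in_range(raw):
            raw = self.fmt.saturate(raw)
        self.raw[index] = raw

    # value access by name -------------------------------------------------
    def __getitem__(self, name: str) -> float:
        return self.fmt.to_float(self.raw[resolve_register(name)])

    def __setitem__(self, name: str, value) -> None:
        self.raw[resolve_register(name)] = self.fmt.quantize(value)

    def get_raw(self, name: str) -> int:
        return self.raw[resolve_register(name)]

    def set_raw(self, name: str, raw: int) -> None:
        self.set(resolve_register(name), raw)

    def exact(self, name: str) -> Fraction:
        return self.fmt.to_fraction(self.raw[resolve_register(name)])

    # book-keeping ---------------------------------------------------------
    def copy(self) -> "RegisterFile":
        out = RegisterFile(self.fmt)
        out.raw = list(self.raw)
        return out

    def dump(self) -> Dict[str, float]:
        return {name: self.fmt.to_float(self.raw[i])
                for i, name in enumerate(REGISTER_NAMES)}

    def assert_in_range(self) -> None:
        for i, raw in enumerate(self.raw):
            if not self.fmt.in_range(raw):
                raise OverflowError(
                    f"register {REGISTER_NAMES[i]} out of range: {raw}")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, RegisterFile) and self.raw == other.raw \
            and self.fmt == other.fmt

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        nz = {REGISTER_NAMES[i]: self.fmt.to_float(v)
              for i, v in enumerate(self.raw) if v}
        return f"RegisterFile({nz})"
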