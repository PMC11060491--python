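"""Discrete-time reference implementations of the supported model family.

These are direct, instruction-free implementations of the discretised
update equations — the oracles against which the ISA programs of
:mod:`darwinsim.programs` are verified bit-for-bit.  Each reference
stepper performs exactly the same sequence of fixed-point operations as
the corresponding program executes, but written as plain arithmetic on
the model's state variables.

The continuous-parameter dataclasses and :func:`euler_map` translate
biophysical constants (time constants, increments, amplitudes) into the
dimensionless discrete coefficients ``p0..p8``, ``c0..c2``,
``P0*..P6*``, ``C0*..C3*`` via a forward-Euler step of size ``dt``:

* membrane:    ``v(t+1) = p0 v + p1 I + p2 v_adp + c0`` with
  ``p0 = 1 - dt/tau_m``, ``p1 = dt/(tau_m g)``, ``p2 = -dt/(tau_m g)``,
  ``c0 = dt E_L / tau_m``;
* adaptation:  ``p3 = 1 - dt/tau_adp``, ``p4 = a dt/tau_adp``,
  ``c1 = -a dt E_L / tau_adp``, ``c2 = b``;
* synapse:     ``p8 = 1 - dt/tau_rise``, ``p5 = 1 - dt/tau_decay``,
  ``p6 = dt``, ``p7 = -E_L`` (current ``I = g v + p7 g``);
* traces:      multipliers ``P* = 1 - dt/tau_*`` and increments
  ``C* = a_* dt/tau_*``; weight amplitudes ``P0* = A_pre``,
  ``P1* = -A_post0``, ``P2* = -A_post1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Dict, List, Optional, Tuple

from .fixed_point import FixedPointFormat
from .isa.pseudo import EXP_BASE, EXP_BINS, build_microcode_rom


# ---------------------------------------------------------------------------
# Continuous parameters and the Euler mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContinuousNeuronParams:
    tau_m: float = 10.0       # membrane time constant
    E_L: float = 0.0          # leak reversal potential
    g: float = 1.0            # leak conductance
    tau_adp: float = 100.0    # adaptation time constant
    a: float = 0.0            # sub-threshold adaptation sensitivity
    b: float = 0.0            # spike-triggered adaptation increment
    v_0: float = 0.0          # reset potential
    v_th: float = 1.0         # firing threshold


@dataclass(frozen=True)
class ContinuousSynapseParams:
    tau_rise: float = 2.0
    tau_decay: float = 8.0
    E_L: float = 0.0


@dataclass(frozen=True)
class ContinuousPlasticityParams:
    tau_pre0: float = 20.0
    tau_post0: float = 20.0
    tau_post1: float = 40.0
    tau_rwd: float = 50.0
    a_pre0: float = 1.0
    a_post0: float = 1.0
    a_post1: float = 1.0
    a_rwd: float = 1.0
    A_pre: float = 0.01
    A_post0: float = 0.01
    A_post1: float = 0.01


@dataclass
class DiscreteParams:
    """Dimensionless coefficients of the discrete updates."""

    p: List[float] = field(default_factory=lambda: [0.0] * 9)   # p0..p8
    c: List[float] = field(default_factory=lambda: [0.0] * 3)   # c0..c2
    P: List[float] = field(default_factory=lambda: [0.0] * 7)   # P0*..P6*
    C: List[float] = field(default_factory=lambda: [0.0] * 4)   # C0*..C3*
    v_0: float = 0.0
    v_th: float = 1.0


def euler_map(cont, dt: float,
              base: Optional[DiscreteParams] = None) -> DiscreteParams:
    """Forward-Euler mapping of continuous parameters to discrete
    coefficients; accepts any of the three continuous parameter sets and
    fills the corresponding coefficient slots."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    dp = replace(base, p=list(base.p), c=list(base.c), P=list(base.P),
                 C=list(base.C)) if base is not None else DiscreteParams()
    if isinstance(cont, ContinuousNeuronParams):
        taus = [cont.tau_m, cont.tau_adp]
        dp.p[0] = 1.0 - dt / cont.tau_m
        dp.p[1] = dt / (cont.tau_m * cont.g)
        dp.p[2] = -dt / (cont.tau_m * cont.g)
        dp.c[0] = dt * cont.E_L / cont.tau_m
        dp.p[3] = 1.0 - dt / cont.tau_adp
        dp.p[4] = cont.a * dt / cont.tau_adp
        dp.c[1] = -cont.a * dt * cont.E_L / cont.tau_adp
        dp.c[2] = cont.b
        dp.v_0 = cont.v_0
        dp.v_th = cont.v_th
    elif isinstance(cont, ContinuousSynapseParams):
        taus = [cont.tau_rise, cont.tau_decay]
        dp.p[8] = 1.0 - dt / cont.tau_rise
        dp.p[5] = 1.0 - dt / cont.tau_decay
        dp.p[6] = dt
        dp.p[7] = -cont.E_L
    elif isinstance(cont, ContinuousPlasticityParams):
        taus = [cont.tau_pre0, cont.tau_post0, cont.tau_post1, cont.tau_rwd]
        dp.P[3] = 1.0 - dt / cont.tau_pre0
        dp.C[0] = cont.a_pre0 * dt / cont.tau_pre0
        dp.P[4] = 1.0 - dt / cont.tau_post0
        dp.C[1] = cont.a_post0 * dt / cont.tau_post0
        dp.P[5] = 1.0 - dt / cont.tau_post1
        dp.C[2] = cont.a_post1 * dt / cont.tau_post1
        dp.P[6] = 1.0 - dt / cont.tau_rwd
        dp.C[3] = cont.a_rwd * dt / cont.tau_rwd
        dp.P[0] = cont.A_pre
        dp.P[1] = -cont.A_post0
        dp.P[2] = -cont.A_post1
    else:
        raise TypeError(f"unsupported parameter set {type(cont).__name__}")
    if dt >= min(taus):
        warnings.warn(
            f"dt={dt} is not smaller than the fastest time constant "
            f"({min(taus)}); the Euler step may be unstable",
            stacklevel=2)
    return dp


# ---------------------------------------------------------------------------
# Exact (un-quantised) adaptive-LIF step, used by convergence tests
# ---------------------------------------------------------------------------

def adlif_step_exact(v: Fraction, v_adp: Fraction, I: Fraction,
                     dp: DiscreteParams) -> Tuple[Fraction, Fraction, bool]:
    """One exact rational step of the adaptive-LIF update (threshold,
    reset and adaptation included)."""
    fr = Fraction
    v_adp_next = fr(dp.p[3]) * v_adp + fr(dp.p[4]) * v + fr(dp.c[1])
    v_next = (fr(dp.p[0]) * v + fr(dp.p[1]) * I
              + fr(dp.p[2]) * v_adp_next + fr(dp.c[0]))
    spike = v_next > fr(dp.v_th)
    if spike:
        v_adp_next = v_adp_next + fr(dp.c[2])
        v_next = fr(dp.v_0)
    return v_next, v_adp_next, spike


# ---------------------------------------------------------------------------
# Fixed-point helpers shared by the reference steppers
# ---------------------------------------------------------------------------

def quantize_params(fmt: FixedPointFormat,
                    values: Dict[str, float]) -> Dict[str, int]:
    return {k: fmt.quantize(v) for k, v in values.items()}


def exp_fixed(fmt: FixedPointFormat, x_raw: int,
              rom: Optional[Dict[int, int]] = None) -> int:
    """Fixed-point exponential on [-8, 0]: the arithmetic twin of the EXP
    microcode (64-interval LUT with linear interpolation)."""
    rom = rom if rom is not None else build_microcode_rom(fmt)
    f = fmt.fraction_bits
    t = fmt.add(x_raw, 8 << f)
    index = fmt.shift(t, -(f - 3))
    rem = fmt.sub(t, fmt.shift(index, f - 3))
    fb = fmt.shift(rem, 3)
    y0 = rom[EXP_BASE + index]
    y1 = rom[EXP_BASE + index + 1]
    dy = fmt.sub(y1, y0)
    return fmt.add(y0, fmt.mul_round(dy, fb))


# ---------------------------------------------------------------------------
# Reference neuron steppers (bit-exact mirrors of the ISA programs)
# ---------------------------------------------------------------------------

class _RefBase:
    """Common fixed-point state for the neuron references."""

    def __init__(self, fmt: FixedPointFormat, params: Dict[str, float],
                 state: Optional[Dict[str, float]] = None) -> None:
        self.fmt = fmt
        self.P = quantize_params(fmt, params)
        q = fmt.quantize
        state = state or {}
        self.vm = q(state.get("vm", 0.0))
        self.g = q(state.get("g", 0.0))
        self.I = q(state.get("I", 0.0))
        self.h = q(state.get("h", 0.0))
        self.vadp = q(state.get("vadp", 0.0))

    def _fold(self, input_raw: int) -> None:
        f = self.fmt
        self.h = f.add(f.mul(self.P.get("p8", 0), self.h),
                       f.saturate(input_raw))

    def _chain_g(self) -> None:
        f = self.fmt
        self.g = f.add(f.mul(self.P.get("p5", 0), self.g),
                       f.mul(self.P.get("p6", 0), self.h))

    def _current(self, with_gv: bool) -> None:
        f = self.fmt
        acc = 0
        if with_gv:
            acc = f.add(acc, f.mul(self.g, self.vm))
        acc = f.add(acc, f.mul(self.P.get("p7", 0), self.g))
        self.I = acc

    def _threshold(self, adapt: bool) -> bool:
        if self.vm <= self.P["vth"]:
            return False
        if adapt:
            self.vadp = self.fmt.add(self.vadp, self.P.get("c2", 0))
        self.vm = self.P.get("v0", 0)
        return True


class RefLIF(_RefBase):
    """Leaky integrate-and-fire with a current-based dual-exp synapse."""

    with_gv = False
    adaptation = False

    def step(self, input_raw: int) -> Tuple[int, bool]:
        f = self.fmt
        self._fold(input_raw)
        self._chain_g()
        self._current(self.with_gv)
        if self.adaptation:
            self.vadp = f.add(f.add(f.mul(self.P["p3"], self.vadp),
                                    f.mul(self.P["p4"], self.vm)),
                              self.P.get("c1", 0))
            self.vm = f.add(f.add(f.add(f.mul(self.P["p0"], self.vm),
                                        f.mul(self.P["p1"], self.I)),
                                  f.mul(self.P["p2"], self.vadp)),
                            self.P.get("c0", 0))
        else:
            self.vm = f.add(f.add(f.mul(self.P["p0"], self.vm),
                                  f.mul(self.P["p1"], self.I)),
                            self.P.get("c0", 0))
        return self.vm, self._threshold(self.adaptation)


class RefCOBA(RefLIF):
    """Conductance-based dual-exponential synapse: I = g v + p7 g."""

    with_gv = True


class RefAdLIF(RefCOBA):
    """Adaptive LIF over the conductance-based synapse chain."""

    adaptation = True


class RefCUBADelta(_RefBase):
    """Delta synapse: the accumulated input is the synaptic current."""

    def step(self, input_raw: int) -> Tuple[int, bool]:
        f = self.fmt
        self._fold(input_raw)          # p8 = 0: h is the buffered input
        self._chain_g()                # p5 = 0, p6 = 1: g = h
        self._current(False)           # p7 = 1: I = g
        self.vm = f.add(f.add(f.mul(self.P["p0"], self.vm),
                              f.mul(self.P["p1"], self.I)), 0)
        return self.vm, self._threshold(False)


class RefQIF(_RefBase):
    """Quadratic IF via the state-dependent-coefficient pattern:
    the v_m multiplier is itself p1*v_m + c1."""

    def step(self, input_raw: int) -> Tuple[int, bool]:
        f = self.fmt
        self._fold(input_raw)
        self._chain_g()
        self._current(False)
        p0 = f.add(f.mul(self.P["p1"], self.vm), self.P["c1"])
        self.vm = f.add(f.add(f.mul(p0, self.vm),
                              f.mul(self.P["p1"], self.I)),
                        self.P.get("c0", 0))
        return self.vm, self._threshold(False)


class RefExpIF(_RefBase):
    """Exponential IF: the constant drive gains a LUT-exponential term
    scale*exp(p3*v + c1) + offset."""

    def __init__(self, fmt, params, state=None):
        super().__init__(fmt, params, state)
        self.rom = build_microcode_rom(fmt)

    def step(self, input_raw: int) -> Tuple[int, bool]:
        f = self.fmt
        arg = f.add(f.mul(self.P["p3"], self.vm), self.P["c1"])
        e = exp_fixed(f, arg, self.rom)
        e = f.mul_round(e, self.P["exp_scale"])
        c0 = f.add(e, self.P["exp_offset"])
        self._fold(input_raw)
        self._chain_g()
        self._current(False)
        self.vm = f.add(f.add(f.mul(self.P["p0"], self.vm),
                              f.mul(self.P["p1"], self.I)), c0)
        return self.vm, self._threshold(False)


class RefIzhikevich(_RefBase):
    """Two-variable Izhikevich update; the quadratic term enters through
    the state-dependent v_m coefficient p0 = p6*v + c1."""

    def step(self, input_raw: int) -> Tuple[int, bool]:
        f = self.fmt
        self._fold(input_raw)
        self._chain_g()
        self._current(False)
        p0 = f.add(f.mul(self.P["pquad"], self.vm), self.P["c1"])
        self.vadp = f.add(f.mul(self.P["p3"], self.vadp),
                          f.mul(self.P["p4"], self.vm))
        self.vm = f.add(f.add(f.add(f.mul(p0, self.vm),
                                    f.mul(self.P["p1"], self.I)),
                              f.mul(self.P["p2"], self.vadp)),
                        self.P["c0"])
        return self.vm, self._threshold(True)


# ---------------------------------------------------------------------------
# Reference plasticity steppers
# ---------------------------------------------------------------------------

class RefPairSTDP:
    """Pair-based STDP: exponentially decaying pre/post traces, weight
    update gated by the opposite spike flag.

    dw = P0* x0 y2 + P1* y0 x2   (P1* < 0 for depression)
    """

    triplet = False
    rewarded = False

    def __init__(self, fmt: FixedPointFormat, params: Dict[str, float],
                 w0: float = 0.0) -> None:
        self.fmt = fmt
        self.P = quantize_params(fmt, params)
        self.x0 = 0
        self.y0 = 0
        self.y1 = 0
        self.r0 = self.fmt.quantize(params.get("r0_init", 0.0))
        self.w = fmt.quantize(w0)

    def _trace(self, value: int, decay: int, flag: int, inc: int) -> int:
        f = self.fmt
        v = f.add(f.mul(decay, value), 0)
        return f.add(v, f.mul_round(flag, inc))

    def step(self, pre: bool, post: bool, reward: float = 0.0) -> int:
        f = self.fmt
        one = f.one
        x2 = one if pre else 0
        y2 = one if post else 0
        self.x0 = self._trace(self.x0, self.P["Px"], x2, self.P["ax"])
        self.y0 = self._trace(self.y0, self.P["Py0"], y2, self.P["ay0"])
        if self.triplet:
            self.y1 = self._trace(self.y1, self.P["Py1"], y2, self.P["ay1"])
        if self.rewarded:
            r2 = f.quantize(reward)
            self.r0 = self._trace(self.r0, self.P["Pr"], r2, self.P["ar"])
        elif "Pr" in self.P:  # plain triplet: r0 held at its initial value
            self.r0 = f.mul(self.P["Pr"], self.r0)
        # weight terms mirror the UPTWT product order (ascending LS index)
        t1 = f.mul(self.P["A0"], self.x0)      # * x0 (LS0)
        if self.use_r():
            t1 = f.mul(t1, y2)                 # * y2 (LS5)
            t1 = f.mul(t1, self.r0)            # * r0 (LS6)
        else:
            t1 = f.mul(t1, y2)
        self.w = f.add(self.w, t1)
        t2 = f.mul(self.P["A1"], x2)           # * x2 (LS2)
        t2 = f.mul(t2, self.y0)                # * y0 (LS3)
        if self.use_r():
            t2 = f.mul(t2, self.r0)
        self.w = f.add(self.w, t2)
        if self.triplet:
            t3 = f.mul(self.P["A2"], x2)
            t3 = f.mul(t3, self.y1)            # * y1 (LS4)
            t3 = f.mul(t3, self.r0)
            self.w = f.add(self.w, t3)
        return self.w

    def use_r(self) -> bool:
        return self.triplet or self.rewarded

    @property
    def traces(self) -> Tuple[int, int, int, int]:
        return self.x0, self.y0, self.y1, self.r0


class RefTripletSTDP(RefPairSTDP):
    """Triplet STDP: adds the second post trace y1 and its depression
    term; the reward trace is held constant at 1 (ungated)."""

    triplet = True


class RefRSTDP(RefPairSTDP):
    """Reward-modulated pair STDP: the reward trace r0 integrates the
    reward input r2 and multiplicatively gates every weight term."""

    rewarded = True


def ref_triplet_rstdp_step(ref: RefPairSTDP, pre: bool, post: bool,
                           reward: float = 0.0) -> Tuple[Tuple[int, ...], int]:
    """Functional wrapper: advance one step, return (traces, weight)."""
    w = ref.step(pre, post, reward)
    return ref.traces, w


class RefSDSP:
    """Spike-driven synaptic plasticity, four-branch decision rule.

    A calcium-like trace C (decay ``Pc``, post-spike increment ``ac``)
    gates a fixed-step weight change when the post neuron is
    depolarised: with ``v_m >= thr_v`` and ``thr_lo <= C <= thr_hi``,
    the weight steps up if ``C > thr_split`` and down otherwise.
    """

    def __init__(self, fmt: FixedPointFormat, params: Dict[str, float],
                 w0: float = 0.0) -> None:
        self.fmt = fmt
        self.P = quantize_params(fmt, params)
        self.ca = 0
        self.w = fmt.quantize(w0)

    def decide(self, vm_raw: int, ca_raw: int) -> int:
        """The branch rule alone: -1 depress, 0 keep, +1 potentiate."""
        P = self.P
        if P["thr_v"] > vm_raw:
            return 0
        if P["thr_lo"] > ca_raw:
            return 0
        if ca_raw > P["thr_hi"]:
            return 0
        return 1 if ca_raw > P["thr_split"] else -1

    def step(self, vm_raw: int, post: bool) -> int:
        f = self.fmt
        y2 = f.one if post else 0
        self.ca = f.add(f.mul(self.P["Pc"], self.ca), 0)
        self.ca = f.add(self.ca, f.mul_round(y2, self.P["ac"]))
        d = self.decide(vm_raw, self.ca)
        if d > 0:
            self.w = f.add(self.w, self.P["step"])
        elif d < 0:
            self.w = f.sub(self.w, self.P["step"])
        return self.w


class RefSTPHidden:
    """Hidden-layer target-propagation-style rule: a state-dependent
    learning rate (p0*v_m + c0) multiplies the two reward traces."""

    def __init__(self, fmt: FixedPointFormat, params: Dict[str, float],
                 w0: float = 0.0) -> None:
        self.fmt = fmt
        self.P = quantize_params(fmt, params)
        self.w = fmt.quantize(w0)

    def step(self, vm_raw: int, r0_raw: int, r1_raw: int) -> int:
        f = self.fmt
        rate = f.add(f.mul(self.P["p0"], vm_raw), self.P["c0"])
        t = f.mul(rate, r0_raw)
        t = f.mul(t, r1_raw)
        self.w = f.add(self.w, t)
        return self.w
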