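"""Bit-exact verification of ISA programs against their reference models.

For each entry of :data:`darwinsim.programs.MODELS` this module runs the
assembled program on a one-neuron core, feeds it a seeded random event
schedule, runs the direct reference stepper on the same schedule, and
demands raw fixed-point equality of every state variable at every step.
This is the headline correctness surface of the simulator: the
instruction path and the equation path must agree exactly, including
saturation and rounding.
"""

from __future__ import annotations

from typing import Dict, List, Optional

import numpy as np

from .engine import NeuronCore
from .programs import MODELS, ModelSpec


class EquivalenceError(AssertionError):
    pass


def _check(cond: bool, model: str, step: int, what: str, got, want) -> None:
    if not cond:
        raise EquivalenceError(
            f"{model}: step {step}: {what} diverged: program={got} "
            f"reference={want}")


def _verify_neuron(spec: ModelSpec, steps: int, seed: int) -> int:
    fmt = spec.fmt
    core = NeuronCore(1, spec.program, fmt, mode="inference")
    core.init_registers(spec.registers)
    for name, value in spec.state_init.items():
        idx = {"vm": "S0", "g": "S1", "I": "S2", "h": "S3", "vadp": "S4"}[name]
        core.registers[0][idx] = value
    ref = spec.reference(fmt, spec.ref_params, spec.state_init)
    rng = np.random.default_rng(seed)
    amp_raw = fmt.quantize(spec.input_amplitude)
    checked = 0
    for t in range(steps):
        spike_in = rng.random() < spec.input_rate
        input_raw = amp_raw if spike_in else 0
        if input_raw:
            core.accumulate_input(0, input_raw)
        fired = core.step()
        _, ref_spike = ref.step(input_raw)
        regs = core.registers[0]
        _check(bool(fired) == ref_spike, spec.name, t, "spike",
               bool(fired), ref_spike)
        for reg, attr in (("S0", "vm"), ("S1", "g"), ("S2", "I"),
                          ("S3", "h"), ("S4", "vadp")):
            _check(regs.get_raw(reg) == getattr(ref, attr), spec.name, t,
                   reg, regs.get_raw(reg), getattr(ref, attr))
        checked += 1
    return checked


def _verify_learning(spec: ModelSpec, steps: int, seed: int) -> int:
    fmt = spec.fmt
    core = NeuronCore(1, spec.program, fmt, mode="both")
    core.init_registers(spec.registers)
    syn = core.add_synapse("pre", 0, weight_raw=0, ls_init=spec.ls_init)
    ref = spec.reference(fmt, spec.ref_params, 0.0)
    rng = np.random.default_rng(seed)
    drive_raw = fmt.quantize(8.0)
    vth_raw = fmt.quantize(spec.ref_params["vth"])
    rewarded = spec.name == "rstdp"
    checked = 0
    for t in range(steps):
        pre = bool(rng.random() < 0.2)
        drive = bool(rng.random() < 0.25)
        reward = float(rng.integers(0, 8)) / 8.0 if rewarded else 0.0
        w_prev = ref.w
        if pre:
            core.deliver_spike("pre", 0)
        if drive:
            core.accumulate_input(0, drive_raw)
        if rewarded:
            core.set_reward(0, reward)
        fired = core.step()
        # mirror of the post-driver neuron: v_m equals the saturated input
        input_raw = (drive_raw if drive else 0) + (w_prev if pre else 0)
        vm_mirror = fmt.saturate(input_raw)
        post = vm_mirror > vth_raw
        _check(bool(fired) == post, spec.name, t, "post spike",
               bool(fired), post)
        if spec.name == "sdsp":
            ref.step(vm_mirror, post)
            _check(syn.ls[1] == ref.ca, spec.name, t, "calcium",
                   syn.ls[1], ref.ca)
        elif spec.name == "stp_hidden":
            ref.step(vm_mirror, fmt.quantize(0.5), fmt.quantize(0.25))
        else:
            ref.step(pre, post, reward)
            _check(syn.ls[0] == ref.x0, spec.name, t, "x0",
                   syn.ls[0], ref.x0)
            _check(syn.ls[3] == ref.y0, spec.name, t, "y0",
                   syn.ls[3], ref.y0)
            _check(syn.ls[4] == ref.y1, spec.name, t, "y1",
                   syn.ls[4], ref.y1)
            _check(syn.ls[6] == ref.r0, spec.name, t, "r0",
                   syn.ls[6], ref.r0)
        _check(syn.weight == ref.w, spec.name, t, "weight",
               syn.weight, ref.w)
        checked += 1
    return checked


def verify_model(name: str, steps: int = 1000, seed: int = 0) -> int:
    """Run one model's program against its reference; returns the number
    of verified steps, raises :class:`EquivalenceError` on divergence."""
    spec = MODELS[name]
    if spec.kind == "neuron":
        return _verify_neuron(spec, steps, seed)
    return _verify_learning(spec, steps, seed)


def verify_all(steps: int = 1000, seeds=range(10),
               names: Optional[List[str]] = None) -> Dict[str, int]:
    """Verify every registered model over several seeds; returns the
    total verified step count per model."""
    totals: Dict[str, int] = {}
    for name in names or list(MODELS):
        total = 0
        for seed in seeds:
            total += verify_model(name, steps=steps, seed=seed)
        totals[name] = total
    return totals
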