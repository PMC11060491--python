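"""Whole-chip orchestration: configuration, the global tick, and capture.

A chip is a mesh of neuron cores (node (0, 0) is the management node and
runs no neurons) plus the spike-routing fabric.  Each global time step:

1. external stimuli scheduled for this step are accumulated;
2. packets injected during the previous step are delivered: the target
   core resolves its axon-in entry to (neuron, weight) events;
3. every core advances one step (input fold, inference in ascending
   neuron order, learning);
4. fired neurons look up their axon-out chains and inject one packet
   per (target core, axon-in index) into the mesh, to be delivered at
   the start of the next step.

Spike delivery is therefore visible to the receiving core at the step
after firing, uniformly for local and remote targets; the cycle-level
transmission latency of a path is available from the NoC model but does
not reorder step-level delivery (congestion is not modelled).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple, Union

import yaml

from .connectivity import (
    ConnectionList,
    CoreGeometry,
    CoreTables,
    D2_DEFAULT,
    D1_LARGE_TILE,
    Edge,
    build_tables,
    lookup_axon_out,
    max_fan_in,
    max_fan_out,
    resolve_axon_in,
)
from .engine import MAX_NEURONS_PER_CORE, EngineError, NeuronCore
from .fixed_point import FixedPointFormat
from .isa.asm import Program, assemble, disassemble
from .noc import MANAGEMENT_NODE, MESH_DIMS, Mesh, SpikePacket

Coord = Tuple[int, int]


class ConfigError(ValueError):
    pass


@dataclass
class NeuronCoreConfig:
    coord: Coord
    neuron_count: int
    program: Program
    mode: str = "inference"
    registers: Dict[str, float] = field(default_factory=dict)
    neuron_registers: Dict[int, Dict[str, float]] = field(default_factory=dict)
    weight_width: int = 16
    d1: int = D1_LARGE_TILE
    d2: int = D2_DEFAULT
    total_bits: int = 16
    fraction_bits: int = 8

    @property
    def geometry(self) -> CoreGeometry:
        return CoreGeometry(D1=self.d1, D2=self.d2, N=self.neuron_count)

    @property
    def fmt(self) -> FixedPointFormat:
        return FixedPointFormat(self.total_bits, self.fraction_bits)


@dataclass
class ChipConfig:
    mesh_dims: Coord = MESH_DIMS
    cores: List[NeuronCoreConfig] = field(default_factory=list)
    connections: ConnectionList = field(default_factory=ConnectionList)
    # (step, core coord, neuron id, weight value)
    stimuli: List[Tuple[int, Coord, int, float]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        seen = set()
        w, h = self.mesh_dims
        for cc in self.cores:
            if cc.coord == MANAGEMENT_NODE:
                raise ConfigError(
                    f"core {cc.coord}: node (0, 0) is the management node")
            if not (0 <= cc.coord[0] < w and 0 <= cc.coord[1] < h):
                raise ConfigError(f"core {cc.coord}: outside {self.mesh_dims}")
            if cc.coord in seen:
                raise ConfigError(f"core {cc.coord}: duplicate definition")
            seen.add(cc.coord)
            if not 1 <= cc.neuron_count <= MAX_NEURONS_PER_CORE:
                raise ConfigError(
                    f"core {cc.coord}: neuron count {cc.neuron_count} "
                    f"outside 1..{MAX_NEURONS_PER_CORE}")
        by_coord = {cc.coord: cc for cc in self.cores}
        for e in self.connections:
            for side, core, nid in (("pre", e.pre_core, e.pre_id),
                                    ("post", e.post_core, e.post_id)):
                if core not in by_coord:
                    raise ConfigError(
                        f"connection {side} core {core} is not configured")
                if nid >= by_coord[core].neuron_count:
                    raise ConfigError(
                        f"connection {side} neuron {nid} exceeds core "
                        f"{core} count {by_coord[core].neuron_count}")


@dataclass(frozen=True)
class SpikeRecord:
    step: int
    core: Coord
    neuron: int


class Chip:
    """A configured chip ready to run."""

    def __init__(self, config: ChipConfig) -> None:
        config.validate()
        self.config = config
        self.mesh = Mesh(config.mesh_dims)
        self.cores: Dict[Coord, NeuronCore] = {}
        geometry = {cc.coord: cc.geometry for cc in config.cores}
        self.tables: Dict[Coord, CoreTables] = build_tables(
            config.connections, geometry)
        for cc in config.cores:
            core = NeuronCore(cc.neuron_count, cc.program, cc.fmt,
                              mode=cc.mode, coord=cc.coord)
            core.init_registers(cc.registers)
            for nid, values in cc.neuron_registers.items():
                core.init_registers(values, neurons=[nid])
            self.cores[cc.coord] = core
        # learning cores hold per-synapse records (authoritative weights)
        for e in config.connections:
            post = self.cores[e.post_core]
            if post.mode in ("learning", "both"):
                post.add_synapse((e.pre_core, e.pre_id), e.post_id,
                                 e.weight, e.width)
        self._stimuli: Dict[int, List[Tuple[Coord, int, float]]] = {}
        for step, coord, nid, value in config.stimuli:
            self._stimuli.setdefault(step, []).append((coord, nid, value))
        self.step_index = 0

    # -- per-step machinery ----------------------------------------------
    def inject_stimulus(self, core: Coord, neuron: int, value: float) -> None:
        c = self.cores[core]
        c.accumulate_input(neuron, c.fmt.quantize(value))

    def _deliver_in_flight(self) -> None:
        for _cycle, node, packet in self.mesh.drain():
            if node not in self.cores:
                if node == MANAGEMENT_NODE:
                    continue  # management node sinks stray traffic
                raise ConfigError(f"packet delivered to unconfigured {node}")
            core = self.cores[node]
            table = self.tables[node].axon_in
            for post_id, weight in resolve_axon_in(
                    table, packet.axon_in_index, packet.source_index):
                core.deliver_spike((packet.src_core, packet.src_neuron),
                                   post_id, weight)

    def _emit(self, coord: Coord, neuron: int) -> None:
        table = self.tables.get(coord)
        if table is None:
            return
        for offset, idx, src_index in lookup_axon_out(table.axon_out, neuron):
            self.mesh.inject(coord, SpikePacket(
                offset=offset, axon_in_index=idx, source_index=src_index,
                src_core=coord, src_neuron=neuron,
                issue_step=self.step_index))

    def tick(self) -> List[SpikeRecord]:
        """Advance the whole chip by one global time step."""
        self.step_index += 1
        for coord, nid, value in self._stimuli.get(self.step_index, []):
            self.inject_stimulus(coord, nid, value)
        self._deliver_in_flight()
        records: List[SpikeRecord] = []
        for coord in sorted(self.cores):
            fired = self.cores[coord].step()
            for neuron in fired:
                records.append(SpikeRecord(self.step_index, coord, neuron))
                self._emit(coord, neuron)
        return records

    def run(self, steps: int) -> List[SpikeRecord]:
        if steps < 0:
            raise ValueError("steps must be non-negative")
        out: List[SpikeRecord] = []
        for _ in range(steps):
            out.extend(self.tick())
        return out

    # -- inspection -------------------------------------------------------
    def learned_weight(self, pre: Tuple[Coord, int],
                       post: Tuple[Coord, int]) -> int:
        core = self.cores[post[0]]
        syn = core.synapses.get(post[1], {}).get(pre)
        if syn is None:
            raise KeyError(f"no synapse {pre} -> {post}")
        return syn.weight


def spikes_to_frame(records: Iterable[SpikeRecord]):
    import pandas as pd

    return pd.DataFrame(
        [(r.step, r.core[0], r.core[1], r.neuron) for r in records],
        columns=["step", "core_x", "core_y", "neuron"])


# ---------------------------------------------------------------------------
# Capacity accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CapacityReport:
    mesh_dims: Coord
    neuron_cores: int
    neurons_per_core: int
    total_neurons: int
    max_fan_in_per_core: int
    max_fan_out_per_core: int

    @property
    def total_neurons_millions(self) -> float:
        return round(self.total_neurons / 1e6, 2)


def capacity_report(mesh_dims: Coord = MESH_DIMS,
                    neurons_per_core: int = MAX_NEURONS_PER_CORE,
                    d1: int = D1_LARGE_TILE,
                    d2: int = D2_DEFAULT) -> CapacityReport:
    """Chip-level capacity totals for a mesh geometry: every node except
    the management node at (0, 0) is a neuron core."""
    w, h = mesh_dims
    if w < 1 or h < 1:
        raise ValueError("mesh dimensions must be positive")
    cores = w * h - 1
    return CapacityReport(
        mesh_dims=mesh_dims,
        neuron_cores=cores,
        neurons_per_core=neurons_per_core,
        total_neurons=cores * neurons_per_core,
        max_fan_in_per_core=max_fan_in(d1, neurons_per_core),
        max_fan_out_per_core=max_fan_out(d2, neurons_per_core),
    )


# ---------------------------------------------------------------------------
# Configuration files (YAML)
# ---------------------------------------------------------------------------

def _config_to_dict(config: ChipConfig) -> dict:
    cores = []
    for cc in config.cores:
        cores.append({
            "coord": list(cc.coord),
            "neurons": cc.neuron_count,
            "mode": cc.mode,
            "program": disassemble(cc.program),
            "registers": dict(cc.registers),
            "neuron_registers": {int(k): dict(v)
                                 for k, v in cc.neuron_registers.items()},
            "weight_width": cc.weight_width,
            "d1": cc.d1,
            "d2": cc.d2,
            "fixed_point": {"total_bits": cc.total_bits,
                            "fraction_bits": cc.fraction_bits},
        })
    return {
        "mesh": list(config.mesh_dims),
        "seed": config.seed,
        "cores": cores,
        "connections": [[e.pre_core[0], e.pre_core[1], e.pre_id,
                         e.post_core[0], e.post_core[1], e.post_id,
                         e.weight, e.width] for e in config.connections],
        "stimuli": [[step, coord[0], coord[1], nid, float(value)]
                    for step, coord, nid, value in config.stimuli],
    }


def save_config(config: ChipConfig, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=False)


def _core_from_dict(d: dict) -> NeuronCoreConfig:
    try:
        coord = tuple(d["coord"])
        fp = d.get("fixed_point", {})
        return NeuronCoreConfig(
            coord=coord,
            neuron_count=int(d["neurons"]),
            program=assemble(d["program"]),
            mode=d.get("mode", "inference"),
            registers={str(k): float(v)
                       for k, v in (d.get("registers") or {}).items()},
            neuron_registers={int(k): {str(n): float(v) for n, v in vv.items()}
                              for k, vv in
                              (d.get("neuron_registers") or {}).items()},
            weight_width=int(d.get("weight_width", 16)),
            d1=int(d.get("d1", D1_LARGE_TILE)),
            d2=int(d.get("d2", D2_DEFAULT)),
            total_bits=int(fp.get("total_bits", 16)),
            fraction_bits=int(fp.get("fraction_bits", 8)),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ConfigError(
            f"core {d.get('coord', '?')}: invalid configuration: {exc}"
        ) from exc


def load_config(source: Union[str, Path, io.TextIOBase]) -> ChipConfig:
    """Load and fully validate a chip configuration (programs assembled,
    connections checked against core geometry)."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh)
    else:
        data = yaml.safe_load(source)
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    cores = [_core_from_dict(d) for d in data.get("cores", [])]
    edges = []
    conn = data.get("connections", [])
    if isinstance(conn, dict) and "csv" in conn:
        connections = ConnectionList.from_csv(conn["csv"])
    else:
        for row in conn:
            px, py, pid, qx, qy, qid, w, width = row
            edges.append(Edge((int(px), int(py)), int(pid),
                              (int(qx), int(qy)), int(qid),
                              int(w), int(width)))
        connections = ConnectionList(edges)
    stimuli = [(int(s), (int(x), int(y)), int(n), float(v))
               for s, x, y, n, v in data.get("stimuli", [])]
    config = ChipConfig(
        mesh_dims=tuple(data.get("mesh", MESH_DIMS)),
        cores=cores,
        connections=connections,
        stimuli=stimuli,
        seed=int(data.get("seed", 0)),
    )
    config.validate()
    # building the tables checks connectivity capacity up front
    build_tables(connections, {cc.coord: cc.geometry for cc in cores})
    return config
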