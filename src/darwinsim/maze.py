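"""STDP maze solving on the simulated chip.

A maze is mapped one neuron per grid cell: excitatory neurons represent
free cells, inhibitory neurons (modelled as neurons whose threshold is
unreachable, so they never fire) represent obstacles, and every pair of
4-adjacent cells is connected in both directions.  A single stimulus at
the start cell launches a spike wavefront that spreads one cell per time
step; propagation halts at inhibitory neurons.  The learning rule
``w += A * x2 * y2`` potentiates a synapse exactly when its pre-synaptic
neuron fired one step before the post-synaptic neuron, i.e. precisely on
the causal front of the wave, so the strengthened edge into any cell
points back at a breadth-first predecessor.  Walking the strengthened
edges backwards from the goal therefore reads out a shortest path, which
on a perfect maze is the unique path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .chip import Chip, ChipConfig, NeuronCoreConfig, SpikeRecord
from .connectivity import CapacityError, ConnectionList, Edge
from .engine import MAX_NEURONS_PER_CORE
from .isa.asm import Program
from .noc import MANAGEMENT_NODE, MESH_DIMS
from .programs import (
    GSPRS_CMP,
    GSPRS_FIRE,
    GSPRS_RESET,
    UPTIS_P6,
    UPTIS_P7,
    UPTVM_I,
    UPTVM_VM,
    gsprs,
    uptis,
    uptvm,
    uptwt,
)

Cell = Tuple[int, int]  # (x, y)

#: neighbour scan order used for deterministic tie-breaking
NEIGHBOUR_ORDER = ((0, -1), (1, 0), (0, 1), (-1, 0))  # N, E, S, W

_OBSTACLE_THRESHOLD = 120.0   # unreachable in Q8.8 wavefront dynamics
_FREE_THRESHOLD = 0.5
_RESET_POTENTIAL = -8.0
_EDGE_WEIGHT_RAW = 256        # 1.0 in Q8.8
_LEARN_RATE = 0.25


@dataclass
class MazeGrid:
    """Occupancy grid; ``free[y, x]`` is True for walkable cells."""

    width: int
    height: int
    free: np.ndarray
    start: Cell
    goal: Cell
    seed: Optional[int] = None
    style: str = "perfect"

    def is_free(self, cell: Cell) -> bool:
        x, y = cell
        return 0 <= x < self.width and 0 <= y < self.height \
            and bool(self.free[y, x])

    def cell_id(self, cell: Cell) -> int:
        return cell[1] * self.width + cell[0]

    # text format: '.' free, '#' obstacle, 'S' start, 'G' goal ------------
    def to_text(self) -> str:
        rows = []
        for y in range(self.height):
            row = []
            for x in range(self.width):
                if (x, y) == self.start:
                    row.append("S")
                elif (x, y) == self.goal:
                    row.append("G")
                else:
                    row.append("." if self.free[y, x] else "#")
            rows.append("".join(row))
        return "\n".join(rows) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "MazeGrid":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        height, width = len(lines), len(lines[0])
        free = np.zeros((height, width), dtype=bool)
        start = goal = None
        for y, line in enumerate(lines):
            if len(line) != width:
                raise ValueError("ragged maze rows")
            for x, ch in enumerate(line):
                if ch == "S":
                    start = (x, y)
                    free[y, x] = True
                elif ch == "G":
                    goal = (x, y)
                    free[y, x] = True
                elif ch == ".":
                    free[y, x] = True
                elif ch != "#":
                    raise ValueError(f"unknown cell character {ch!r}")
        if start is None or goal is None:
            raise ValueError("maze must contain S and G")
        return cls(width, height, free, start, goal)


def generate_maze(width: int, height: int, seed: int = 0,
                  style: str = "perfect") -> MazeGrid:
    """Reproducible random maze; always solvable.

    ``perfect`` mazes have tree-structured free cells (a unique path
    between any two); ``braided`` mazes additionally open a fraction of
    walls, creating loops.  Carving runs on the odd-coordinate lattice,
    so odd dimensions use the full area.
    """
    if width < 2 or height < 2:
        raise ValueError("maze must be at least 2x2")
    if style not in ("perfect", "braided"):
        raise ValueError(f"unknown maze style {style!r}")
    rng = np.random.default_rng(seed)
    free = np.zeros((height, width), dtype=bool)
    nodes = [(x, y) for y in range(1, height - 1, 2)
             for x in range(1, width - 1, 2)]
    if not nodes:
        free[:] = True  # degenerate small maze: open field
    else:
        # depth-first spanning tree over the odd lattice
        start_node = nodes[0]
        free[start_node[1], start_node[0]] = True
        stack = [start_node]
        visited = {start_node}
        while stack:
            x, y = stack[-1]
            candidates = []
            for dx, dy in NEIGHBOUR_ORDER:
                nxt = (x + 2 * dx, y + 2 * dy)
                if (1 <= nxt[0] < width - 1 and 1 <= nxt[1] < height - 1
                        and nxt not in visited):
                    candidates.append((dx, dy, nxt))
            if not candidates:
                stack.pop()
                continue
            dx, dy, nxt = candidates[rng.integers(len(candidates))]
            free[y + dy, x + dx] = True
            free[nxt[1], nxt[0]] = True
            visited.add(nxt)
            stack.append(nxt)
        if style == "braided":
            walls = [(x, y) for y in range(1, height - 1)
                     for x in range(1, width - 1)
                     if not free[y, x]
                     and ((free[y, x - 1] and free[y, x + 1])
                          or (free[y - 1, x] and free[y + 1, x]))]
            n_open = max(1, len(walls) // 8)
            for i in rng.choice(len(walls), size=min(n_open, len(walls)),
                                replace=False):
                x, y = walls[i]
                free[y, x] = True
    cells = [(x, y) for y in range(height) for x in range(width)
             if free[y, x]]
    maze = MazeGrid(width, height, free, cells[0], cells[-1],
                    seed=seed, style=style)
    return maze


def bfs_oracle(maze: MazeGrid) -> Optional[List[Cell]]:
    """Breadth-first shortest path over free cells (the search oracle);
    None when the goal is unreachable."""
    graph = nx.Graph()
    for y in range(maze.height):
        for x in range(maze.width):
            if not maze.free[y, x]:
                continue
            graph.add_node((x, y))
            for dx, dy in ((1, 0), (0, 1)):
                if maze.is_free((x + dx, y + dy)):
                    graph.add_edge((x, y), (x + dx, y + dy))
    try:
        return nx.shortest_path(graph, maze.start, maze.goal)
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        return None


# ---------------------------------------------------------------------------
# Mapping onto the chip
# ---------------------------------------------------------------------------

def network_size(width: int, height: int,
                 neurons_per_core: int = MAX_NEURONS_PER_CORE
                 ) -> Dict[str, int]:
    """Sizing metadata for a maze mapping (no network is built)."""
    neurons = width * height
    return {"neurons": neurons,
            "cores": -(-neurons // neurons_per_core),
            "neurons_per_core": neurons_per_core}


def _wavefront_program() -> Program:
    inference = [
        uptis(0b010, UPTIS_P6),        # g = h (accumulated input)
        uptis(0b001, UPTIS_P7),        # I = g
        uptvm(UPTVM_VM | UPTVM_I),     # v += I   (p0 = p1 = 1)
        gsprs(GSPRS_FIRE | GSPRS_CMP | GSPRS_RESET),
    ]
    learning = [uptwt(0, 0b000100100)]  # w += A * x2 * y2 (LS2, LS5)
    return Program(inference, learning)


def maze_to_network(maze: MazeGrid,
                    mesh_dims: Tuple[int, int] = MESH_DIMS,
                    neurons_per_core: int = MAX_NEURONS_PER_CORE
                    ) -> ChipConfig:
    """One neuron per cell (excitatory = free, inhibitory = obstacle),
    bidirectional 4-neighbour synapses, STDP enabled; cells pack onto
    cores row-major."""
    n_cells = maze.width * maze.height
    n_cores = -(-n_cells // neurons_per_core)
    coords = [(x, y) for y in range(mesh_dims[1]) for x in range(mesh_dims[0])
              if (x, y) != MANAGEMENT_NODE]
    if n_cores > len(coords):
        raise CapacityError(
            f"maze of {n_cells} cells needs {n_cores} cores; mesh "
            f"{mesh_dims} provides {len(coords)}")
    coords = coords[:n_cores]

    def place(cell_id: int) -> Tuple[Tuple[int, int], int]:
        return coords[cell_id // neurons_per_core], cell_id % neurons_per_core

    program = _wavefront_program()
    base_regs = {"IP0": 1.0, "IP1": 1.0, "IP6": 1.0, "IP7": 1.0, "IP8": 0.0,
                 "S5": _FREE_THRESHOLD, "V0": _RESET_POTENTIAL,
                 "LP0": _LEARN_RATE}
    cores: List[NeuronCoreConfig] = []
    overrides: Dict[Tuple[int, int], Dict[int, Dict[str, float]]] = {}
    for y in range(maze.height):
        for x in range(maze.width):
            if not maze.free[y, x]:
                coord, nid = place(y * maze.width + x)
                overrides.setdefault(coord, {})[nid] = {
                    "S5": _OBSTACLE_THRESHOLD}
    for i, coord in enumerate(coords):
        count = min(neurons_per_core, n_cells - i * neurons_per_core)
        cores.append(NeuronCoreConfig(
            coord=coord, neuron_count=count, program=program, mode="both",
            registers=dict(base_regs),
            neuron_registers=overrides.get(coord, {}),
            d1=max(4096, 4 * neurons_per_core + 16),
            d2=max(16384, 8 * neurons_per_core + 16)))

    edges = []
    for y in range(maze.height):
        for x in range(maze.width):
            pre = y * maze.width + x
            pre_core, pre_id = place(pre)
            for dx, dy in NEIGHBOUR_ORDER:
                nx_, ny_ = x + dx, y + dy
                if 0 <= nx_ < maze.width and 0 <= ny_ < maze.height:
                    post = ny_ * maze.width + nx_
                    post_core, post_id = place(post)
                    edges.append(Edge(pre_core, pre_id, post_core, post_id,
                                      _EDGE_WEIGHT_RAW, 16))
    stimuli = [(1, place(maze.cell_id(maze.start))[0],
                place(maze.cell_id(maze.start))[1], 1.0)]
    return ChipConfig(mesh_dims=mesh_dims, cores=cores,
                      connections=ConnectionList(edges), stimuli=stimuli)


@dataclass
class SolveResult:
    success: bool
    path: List[Cell] = field(default_factory=list)
    steps_used: int = 0
    fired_cells: List[Cell] = field(default_factory=list)
    reason: str = ""


def _validate_path(maze: MazeGrid, path: Sequence[Cell]) -> None:
    assert path[0] == maze.start and path[-1] == maze.goal
    for cell in path:
        assert maze.is_free(cell), f"path crosses obstacle at {cell}"
    for a, b in zip(path, path[1:]):
        assert abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1, \
            f"path jumps from {a} to {b}"


def solve_maze(maze: MazeGrid, max_steps: Optional[int] = None,
               mesh_dims: Tuple[int, int] = MESH_DIMS,
               neurons_per_core: int = MAX_NEURONS_PER_CORE) -> SolveResult:
    """Run the wavefront + STDP network and read the path from the
    learned weights (backwards from the goal along strengthened edges)."""
    config = maze_to_network(maze, mesh_dims, neurons_per_core)
    chip = Chip(config)
    if max_steps is None:
        max_steps = maze.width * maze.height + 2
    coords = [cc.coord for cc in config.cores]

    def place(cell: Cell):
        cid = maze.cell_id(cell)
        return coords[cid // neurons_per_core], cid % neurons_per_core

    goal_loc = place(maze.goal)
    fired: List[SpikeRecord] = []
    goal_step = None
    for _ in range(max_steps):
        records = chip.tick()
        fired.extend(records)
        if any((r.core, r.neuron) == goal_loc for r in records):
            goal_step = chip.step_index
            break

    def to_cell(rec: SpikeRecord) -> Cell:
        cid = coords.index(rec.core) * neurons_per_core + rec.neuron
        return (cid % maze.width, cid // maze.width)

    fired_cells = [to_cell(r) for r in fired]
    if goal_step is None:
        return SolveResult(False, steps_used=chip.step_index,
                           fired_cells=fired_cells,
                           reason=f"goal not reached in {max_steps} steps")

    # read out: walk strengthened synapses backwards from the goal
    baseline = _EDGE_WEIGHT_RAW
    path = [maze.goal]
    seen = {maze.goal}
    cell = maze.goal
    while cell != maze.start:
        best: Optional[Cell] = None
        best_w = baseline
        for dx, dy in NEIGHBOUR_ORDER:
            prev = (cell[0] + dx, cell[1] + dy)
            if not maze.is_free(prev) or prev in seen:
                continue
            w = chip.learned_weight(place(prev), place(cell))
            if w > best_w:
                best, best_w = prev, w
        if best is None:
            return SolveResult(False, steps_used=chip.step_index,
                               fired_cells=fired_cells,
                               reason=f"no strengthened edge into {cell}")
        path.append(best)
        seen.add(best)
        cell = best
    path.reverse()
    _validate_path(maze, path)
    return SolveResult(True, path=path, steps_used=chip.step_index,
                       fired_cells=fired_cells)
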