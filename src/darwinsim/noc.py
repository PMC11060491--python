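"""Deterministic functional model of the 2-D mesh network on chip.

Spike events travel as address-event packets carrying the *relative*
offset ``(dx, dy)`` from source to destination node; routers consume the
X component first, then Y (dimension-ordered XY routing), and a packet
is delivered exactly when its remaining offset is ``(0, 0)``.  Because
the scheme is relative, a packet whose offset leaves the mesh simply
continues in the neighbouring chip with its residual offset — no address
translation is needed at chip boundaries.

Transmission delay through ``N`` routers is ``2N + 2(N+1)`` cycles
(two per router plus two per asynchronous interconnection, of which
there is one more than routers).  Routers forward one packet per output
per cycle with unbounded FIFOs; congestion is not modelled, so delivery
time is exactly the path latency and delivery order is FIFO by arrival
with ties broken by (source core, source neuron).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Tuple

Coord = Tuple[int, int]

MESH_DIMS = (24, 24)
MANAGEMENT_NODE = (0, 0)


class RoutingError(ValueError):
    pass


@dataclass(frozen=True)
class SpikePacket:
    """An address-event spike in flight."""

    offset: Coord              # remaining (dx, dy) to the destination
    axon_in_index: int
    source_index: int = 0
    src_core: Coord = (0, 0)
    src_neuron: int = 0
    issue_step: int = 0
    issue_cycle: int = 0


def hop_latency(n_routers: int) -> int:
    """Cycles through ``n_routers`` routers and ``n_routers + 1``
    asynchronous interconnections: 2N + 2(N + 1)."""
    if n_routers < 0:
        raise ValueError("router count must be non-negative")
    return 2 * n_routers + 2 * (n_routers + 1)


def route_path(src: Coord, dst: Coord,
               dims: Coord = MESH_DIMS) -> List[Coord]:
    """Ordered routers visited from src to dst under XY routing (source
    router included); length is Manhattan distance + 1."""
    for name, (x, y) in (("src", src), ("dst", dst)):
        if not (0 <= x < dims[0] and 0 <= y < dims[1]):
            raise RoutingError(f"{name} {x, y} is off the {dims} mesh")
    path = [src]
    x, y = src
    step_x = 1 if dst[0] > x else -1
    while x != dst[0]:
        x += step_x
        path.append((x, y))
    step_y = 1 if dst[1] > y else -1
    while y != dst[1]:
        y += step_y
        path.append((x, y))
    return path


@dataclass(frozen=True)
class BoundaryRecord:
    """Serialized form of a packet leaving the mesh at one edge.

    ``lane`` is the row (E/W exits) or column (N/S exits) at which the
    packet crosses; relative routing re-enters the neighbouring chip in
    the same lane with the residual offset unchanged.
    """

    edge: str                  # "E" | "W" | "N" | "S"
    packet: SpikePacket        # residual offset already reduced
    lane: int = 0


@dataclass(order=True)
class _Flight:
    delivery_cycle: int
    src_core: Coord
    src_neuron: int
    seq: int
    node: Coord = field(compare=False)
    packet: SpikePacket = field(compare=False)


class Mesh:
    """Single-chip mesh carrying packets from injection to delivery."""

    def __init__(self, dims: Coord = MESH_DIMS) -> None:
        self.dims = dims
        self._in_flight: List[_Flight] = []
        self._boundary: List[Tuple[int, BoundaryRecord]] = []
        self._seq = 0
        self.cycle = 0

    # -- geometry --------------------------------------------------------
    def contains(self, node: Coord) -> bool:
        return 0 <= node[0] < self.dims[0] and 0 <= node[1] < self.dims[1]

    def _trace(self, src: Coord, offset: Coord
               ) -> Tuple[Optional[Coord], Optional[str], Coord, int, int]:
        """Follow the XY path; returns (delivery node | None, exit edge,
        residual offset, routers traversed on this chip, exit lane)."""
        x, y = src
        dx, dy = offset
        routers = 1  # the source router
        # X phase
        if dx > 0:
            to_edge = self.dims[0] - 1 - x
            if dx > to_edge:
                routers += to_edge
                return None, "E", (dx - to_edge - 1, dy), routers, y
            x += dx
            routers += dx
        elif dx < 0:
            if -dx > x:
                routers += x
                return None, "W", (dx + x + 1, dy), routers, y
            x += dx
            routers += -dx
        # Y phase
        if dy > 0:
            to_edge = self.dims[1] - 1 - y
            if dy > to_edge:
                routers += to_edge
                return None, "N", (0, dy - to_edge - 1), routers, x
            y += dy
            routers += dy
        elif dy < 0:
            if -dy > y:
                routers += y
                return None, "S", (0, dy + y + 1), routers, x
            y += dy
            routers += -dy
        return (x, y), None, (0, 0), routers, x

    # -- traffic ---------------------------------------------------------
    def inject(self, src: Coord, packet: SpikePacket,
               cycle: Optional[int] = None) -> None:
        """Inject a packet at its source node."""
        if not self.contains(src):
            raise RoutingError(f"source {src} is off the {self.dims} mesh")
        cycle = self.cycle if cycle is None else cycle
        node, edge, residual, routers, lane = self._trace(src, packet.offset)
        latency = hop_latency(routers)
        if edge is not None:
            rec = BoundaryRecord(edge, replace(packet, offset=residual), lane)
            self._boundary.append((cycle + latency, rec))
            return
        self._seq += 1
        self._in_flight.append(_Flight(
            delivery_cycle=cycle + latency,
            src_core=packet.src_core, src_neuron=packet.src_neuron,
            seq=self._seq, node=node,
            packet=replace(packet, offset=(0, 0))))

    def advance(self, cycles: int) -> List[Tuple[int, Coord, SpikePacket]]:
        """Advance the network clock; returns (cycle, node, packet)
        deliveries in FIFO order with deterministic tie-breaks."""
        self.cycle += cycles
        due = [f for f in self._in_flight if f.delivery_cycle <= self.cycle]
        self._in_flight = [f for f in self._in_flight
                           if f.delivery_cycle > self.cycle]
        return [(f.delivery_cycle, f.node, f.packet) for f in sorted(due)]

    def drain(self) -> List[Tuple[int, Coord, SpikePacket]]:
        """Deliver everything currently in flight."""
        horizon = max((f.delivery_cycle for f in self._in_flight),
                      default=self.cycle)
        return self.advance(max(0, horizon - self.cycle))

    def boundary_records(self) -> List[Tuple[int, BoundaryRecord]]:
        out, self._boundary = self._boundary, []
        return out

    @property
    def in_flight(self) -> int:
        return len(self._in_flight)


def step_network(mesh: Mesh, cycles: int = 1):
    """Functional façade: advance the mesh and return deliveries."""
    return mesh.advance(cycles)


def boundary_transfer(packet: SpikePacket, edge: str) -> BoundaryRecord:
    """Serialize a packet crossing the given chip edge; the residual
    offset is carried unchanged into the neighbouring chip."""
    if edge not in ("N", "S", "E", "W"):
        raise RoutingError(f"unknown edge {edge!r}")
    return BoundaryRecord(edge, packet)


class MultiChipMesh:
    """A grid of chips whose meshes forward boundary packets to their
    cardinal neighbours; drops (with a diagnostic) if no neighbour."""

    _ENTRY = {"E": ("W", 1, 0), "W": ("E", -1, 0),
              "N": ("S", 0, 1), "S": ("N", 0, -1)}

    def __init__(self, chips: Iterable[Coord],
                 dims: Coord = MESH_DIMS) -> None:
        self.dims = dims
        self.chips: Dict[Coord, Mesh] = {c: Mesh(dims) for c in chips}
        self.dropped: List[Tuple[Coord, BoundaryRecord]] = []

    def inject(self, chip: Coord, src: Coord, packet: SpikePacket,
               cycle: int = 0) -> None:
        self.chips[chip].inject(src, packet, cycle)

    def _reenter(self, chip: Coord, cycle: int, rec: BoundaryRecord) -> None:
        _, cdx, cdy = self._ENTRY[rec.edge]
        neighbour = (chip[0] + cdx, chip[1] + cdy)
        if neighbour not in self.chips:
            self.dropped.append((chip, rec))
            return
        # X-phase exits (E/W) keep their row; Y-phase exits keep the column
        if rec.edge == "E":
            entry = (0, rec.lane)
        elif rec.edge == "W":
            entry = (self.dims[0] - 1, rec.lane)
        elif rec.edge == "N":
            entry = (rec.lane, 0)
        else:
            entry = (rec.lane, self.dims[1] - 1)
        self.chips[neighbour].inject(entry, rec.packet, cycle)

    def run(self, horizon: int) -> List[Tuple[int, Coord, Coord, SpikePacket]]:
        """Deliver all traffic up to the horizon; returns
        (cycle, chip, node, packet) in deterministic order."""
        deliveries: List[Tuple[int, Coord, Coord, SpikePacket]] = []
        for _ in range(8):  # bounded relay passes across chips
            moved = False
            for chip in sorted(self.chips):
                mesh = self.chips[chip]
                for cycle, node, packet in mesh.advance(
                        max(0, horizon - mesh.cycle)):
                    deliveries.append((cycle, chip, node, packet))
                for cycle, rec in mesh.boundary_records():
                    self._reenter(chip, cycle, rec)
                    moved = True
            if not moved:
                break
        deliveries.sort(key=lambda d: (d[0], d[1], d[2],
                                       d[3].src_core, d[3].src_neuron))
        return deliveries
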