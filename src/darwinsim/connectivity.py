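"""Compressed synaptic-connectivity representation.

Connections are stored in two per-core memories.  On the source side the
*axon-out* table maps each firing neuron, through a linker, to a chain of
entries ``(target-node offset, axon-in index, last flag)``; neurons with
identical chains share one chain (case 2#).  On the target side the
*axon-in* table maps each received axon-in index to a typed entry:

* ``1*`` (full):   one source reaches all N neurons of the core — weights
  are stored sequentially with no per-target indexes;
* ``2*`` (shared): several sources reach one neuron with one shared
  weight — a single index plus a single weight;
* ``3*`` (group):  a remote group reaches a target group — one instance
  of the target-index list, weight rows ordered by source rank;
* ``4*`` (range):  one source reaches sequentially numbered targets —
  first index and count, then the weights;
* point:           one source, one target, one weight.

Weight blocks live in a content-addressed pool so identical rows (for
example a convolution kernel shared by every source) are stored once.
Memory is word-addressed (64-bit words); neuron indexes are 12 bits.
The capacity formulas of the flexible scheme are ``(D1-1)*N`` synapses of
fan-in and ``(D2-N)*N`` of fan-out for a core of ``N`` neurons with
axon-in depth ``D1`` and axon-out depth ``D2``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

WORD_BITS = 64
INDEX_BITS = 12
COUNT_BITS = 12

#: Documented defaults: two tile types differ in axon-in memory depth.
D1_SMALL_TILE = 8
D1_LARGE_TILE = 65537
D2_DEFAULT = 16384
N_DEFAULT = 4096

Coord = Tuple[int, int]


class CapacityError(RuntimeError):
    pass


class StructuralError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Connection lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Edge:
    pre_core: Coord
    pre_id: int
    post_core: Coord
    post_id: int
    weight: int          # raw fixed-point value, fits `width` bits signed
    width: int = 16      # 1/2/4/8/16

    def __post_init__(self) -> None:
        if self.width not in (1, 2, 4, 8, 16):
            raise ValueError(f"unsupported weight width {self.width}")
        lo, hi = -(1 << (self.width - 1)), (1 << (self.width - 1)) - 1
        if not lo <= self.weight <= hi:
            raise ValueError(
                f"weight {self.weight} does not fit {self.width} signed bits")


class ConnectionList:
    """A validated set of synapses between (core, neuron) endpoints."""

    def __init__(self, edges: Iterable[Edge] = ()) -> None:
        self.edges: List[Edge] = []
        seen = set()
        for e in edges:
            key = (e.pre_core, e.pre_id, e.post_core, e.post_id)
            if key in seen:
                raise ValueError(f"duplicate connection {key}")
            seen.add(key)
            self.edges.append(e)

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConnectionList):
            return NotImplemented
        return sorted(self.edges) == sorted(other.edges)

    def cores(self) -> set:
        out = set()
        for e in self.edges:
            out.add(e.pre_core)
            out.add(e.post_core)
        return out

    # CSV round trip ------------------------------------------------------
    COLUMNS = ["pre_core_x", "pre_core_y", "pre_id",
               "post_core_x", "post_core_y", "post_id", "weight", "width"]

    def to_frame(self) -> pd.DataFrame:
        rows = [(e.pre_core[0], e.pre_core[1], e.pre_id,
                 e.post_core[0], e.post_core[1], e.post_id,
                 e.weight, e.width) for e in self.edges]
        return pd.DataFrame(rows, columns=self.COLUMNS)

    def to_csv(self, path_or_buf) -> None:
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConnectionList":
        edges = [Edge((int(r.pre_core_x), int(r.pre_core_y)), int(r.pre_id),
                      (int(r.post_core_x), int(r.post_core_y)),
                      int(r.post_id), int(r.weight), int(r.width))
                 for r in df.itertuples()]
        return cls(edges)

    @classmethod
    def from_csv(cls, path_or_buf) -> "ConnectionList":
        return cls.from_frame(pd.read_csv(path_or_buf))


@dataclass(frozen=True)
class CoreGeometry:
    """Per-core memory geometry."""

    D1: int = D1_LARGE_TILE   # axon-in entry-memory depth (words)
    D2: int = D2_DEFAULT      # axon-out linker+entry memory depth (words)
    N: int = N_DEFAULT        # logical neurons

    def __post_init__(self) -> None:
        if self.D1 < 1 or self.N < 1:
            raise ValueError("D1 and N must be positive")
        if self.D2 < self.N:
            raise ValueError("axon-out depth D2 must be at least N")


# ---------------------------------------------------------------------------
# Capacity formulas
# ---------------------------------------------------------------------------

def max_fan_in(D1: int, N: int) -> int:
    """Maximum synapses terminating on one core: (D1 - 1) * N."""
    if D1 < 1 or N < 1:
        raise ValueError("D1 and N must be positive")
    return (D1 - 1) * N


def max_fan_out(D2: int, N: int) -> int:
    """Maximum synapses originating from one core: (D2 - N) * N."""
    if N < 1:
        raise ValueError("N must be positive")
    if D2 < N:
        raise ValueError("axon-out depth D2 must be at least N")
    return (D2 - N) * N


# ---------------------------------------------------------------------------
# Table structures
# ---------------------------------------------------------------------------

@dataclass
class AxonInEntry:
    kind: str                     # "point" | "full" | "shared" | "group" | "range"
    width: int
    block: int                    # index into the weight pool
    index: int = 0                # point/shared: target; range: first target
    count: int = 0                # range: number of targets
    indexes: Tuple[int, ...] = ()  # group: target index list
    rows: int = 1                 # group: number of source ranks

    def index_bits(self) -> int:
        if self.kind in ("point", "shared"):
            return INDEX_BITS
        if self.kind == "full":
            return 0
        if self.kind == "range":
            return INDEX_BITS + COUNT_BITS
        return INDEX_BITS * len(self.indexes)


@dataclass
class AxonInTable:
    geometry: CoreGeometry
    entries: List[AxonInEntry] = field(default_factory=list)
    pool: List[Tuple[int, ...]] = field(default_factory=list)
    _pool_index: Dict[Tuple[Tuple[int, ...], int], int] = field(
        default_factory=dict, repr=False)

    def add_block(self, weights: Sequence[int], width: int) -> int:
        key = (tuple(weights), width)
        if key in self._pool_index:
            return self._pool_index[key]
        self.pool.append(tuple(weights))
        idx = len(self.pool) - 1
        self._pool_index[key] = idx
        return idx

    @property
    def linkers(self) -> List[Tuple[int, str]]:
        """Received axon-in index -> (entry address, connection type)."""
        return [(i, e.kind) for i, e in enumerate(self.entries)]

    def words(self) -> int:
        """Word footprint: one reserved null entry, then per-entry words
        (index part plus owned weight blocks, minimum one word)."""
        owned: Dict[int, int] = {}
        for i, e in enumerate(self.entries):
            owned.setdefault(e.block, i)
        total = 1
        for i, e in enumerate(self.entries):
            bits = e.index_bits()
            if owned.get(e.block) == i:
                bits += len(self.pool[e.block]) * e.width
            total += max(1, -(-bits // WORD_BITS))
        return total


@dataclass(frozen=True)
class AxonOutEntry:
    offset: Coord                 # relative (dx, dy) to the target node
    axon_in_index: int
    last: bool


@dataclass
class AxonOutTable:
    geometry: CoreGeometry
    chains: List[Tuple[AxonOutEntry, ...]] = field(default_factory=list)
    # neuron -> (chain id, source index within shared group)
    linkers: Dict[int, Tuple[int, int]] = field(default_factory=dict)
    _chain_index: Dict[Tuple, int] = field(default_factory=dict, repr=False)

    def set_chain(self, neuron: int, targets: Sequence[Tuple[Coord, int]],
                  src_index: int) -> None:
        entries = tuple(
            AxonOutEntry(offset, idx, last=(i == len(targets) - 1))
            for i, (offset, idx) in enumerate(targets))
        key = tuple((e.offset, e.axon_in_index) for e in entries)
        chain_id = self._chain_index.get(key)
        if chain_id is None:
            self.chains.append(entries)
            chain_id = len(self.chains) - 1
            self._chain_index[key] = chain_id
        self.linkers[neuron] = (chain_id, src_index)

    def entry_words(self) -> int:
        return sum(len(c) for c in self.chains)

    def words(self) -> int:
        """Linker region (one word per neuron slot) plus chain entries."""
        return self.geometry.N + self.entry_words()


@dataclass
class CoreTables:
    axon_out: AxonOutTable
    axon_in: AxonInTable


# ---------------------------------------------------------------------------
# Lookup / resolution
# ---------------------------------------------------------------------------

def lookup_axon_out(table: AxonOutTable,
                    neuron: int) -> List[Tuple[Coord, int, int]]:
    """Targets of one neuron: ordered (offset, axon-in index, source
    index), following the chain to its last-flagged entry."""
    linker = table.linkers.get(neuron)
    if linker is None:
        return []
    chain_id, src_index = linker
    out = []
    for entry in table.chains[chain_id]:
        out.append((entry.offset, entry.axon_in_index, src_index))
        if entry.last:
            break
    return out


def resolve_axon_in(table: AxonInTable, index: int,
                    source_index: int = 0) -> List[Tuple[int, int]]:
    """(target neuron, raw weight) pairs for one received axon-in index."""
    if not 0 <= index < len(table.entries):
        raise StructuralError(f"dangling axon-in index {index}")
    e = table.entries[index]
    block = table.pool[e.block]
    if e.kind == "point" or e.kind == "shared":
        return [(e.index, block[0])]
    if e.kind == "full":
        return list(enumerate(block))
    if e.kind == "range":
        return [(e.index + j, block[j]) for j in range(e.count)]
    if e.kind == "group":
        k = len(e.indexes)
        if e.rows == 1:
            source_index = 0  # private group entry: single weight row
        elif not 0 <= source_index < e.rows:
            raise StructuralError(
                f"source index {source_index} outside group of {e.rows}")
        row = block[source_index * k:(source_index + 1) * k]
        return list(zip(e.indexes, row))
    raise StructuralError(f"unknown entry type {e.kind!r}")


# ---------------------------------------------------------------------------
# Table construction
# ---------------------------------------------------------------------------

def _contiguous(dsts: Sequence[int]) -> bool:
    return len(dsts) > 1 and dsts[-1] - dsts[0] == len(dsts) - 1


def build_tables(conns: ConnectionList,
                 geometry: Optional[Dict[Coord, CoreGeometry]] = None,
                 default_geometry: Optional[CoreGeometry] = None,
                 ) -> Dict[Coord, CoreTables]:
    """Compress a connection list into per-core axon-out/axon-in tables.

    Case selection is greedy by descending compression ratio
    (full > range > group > shared > point); sources with identical
    chains share axon-out entries.  Raises :class:`CapacityError` when a
    core's fan-in/fan-out formula bound or physical word budget is
    exceeded.
    """
    geometry = dict(geometry or {})
    default_geometry = default_geometry or CoreGeometry()

    def geo(core: Coord) -> CoreGeometry:
        return geometry.get(core, default_geometry)

    tables: Dict[Coord, CoreTables] = {}

    def core_tables(core: Coord) -> CoreTables:
        if core not in tables:
            g = geo(core)
            tables[core] = CoreTables(AxonOutTable(g), AxonInTable(g))
        return tables[core]

    # validate neuron ids and collect per-(src core, dst core) groups
    by_pair: Dict[Tuple[Coord, Coord], Dict[int, List[Edge]]] = {}
    fan_in: Dict[Coord, int] = {}
    fan_out: Dict[Coord, int] = {}
    for e in conns:
        for core, nid in ((e.pre_core, e.pre_id), (e.post_core, e.post_id)):
            if not 0 <= nid < geo(core).N:
                raise CapacityError(
                    f"core {core}: neuron id {nid} outside 0..{geo(core).N - 1}")
        by_pair.setdefault((e.pre_core, e.post_core), {}) \
               .setdefault(e.pre_id, []).append(e)
        fan_in[e.post_core] = fan_in.get(e.post_core, 0) + 1
        fan_out[e.pre_core] = fan_out.get(e.pre_core, 0) + 1

    for core, n in fan_in.items():
        g = geo(core)
        if n > max_fan_in(g.D1, g.N):
            raise CapacityError(
                f"core {core}: fan-in {n} exceeds ({g.D1}-1)*{g.N}")
    for core, n in fan_out.items():
        g = geo(core)
        if n > max_fan_out(g.D2, g.N):
            raise CapacityError(
                f"core {core}: fan-out {n} exceeds ({g.D2}-{g.N})*{g.N}")

    # assigned source rank for group (3*) entries: one per source neuron
    assigned_rank: Dict[Tuple[Coord, int], int] = {}
    # per source neuron: ordered chain targets [(offset, axon-in index)]
    pending: Dict[Tuple[Coord, int], List[Tuple[Coord, int]]] = {}

    for (src_core, dst_core) in sorted(by_pair):
        by_src = by_pair[(src_core, dst_core)]
        dst_tab = core_tables(dst_core).axon_in
        n_dst = geo(dst_core).N
        offset = (dst_core[0] - src_core[0], dst_core[1] - src_core[1])

        # group sources by identical (target list, width) signature
        groups: Dict[Tuple, List[Tuple[int, Tuple[int, ...]]]] = {}
        for src_id, edges in by_src.items():
            edges = sorted(edges, key=lambda e: e.post_id)
            widths = {e.width for e in edges}
            if len(widths) > 1:
                # mixed widths: split per width
                for w in sorted(widths):
                    sub = [e for e in edges if e.width == w]
                    sig = (tuple(e.post_id for e in sub), w)
                    groups.setdefault(sig, []).append(
                        (src_id, tuple(e.weight for e in sub)))
            else:
                sig = (tuple(e.post_id for e in edges), edges[0].width)
                groups.setdefault(sig, []).append(
                    (src_id, tuple(e.weight for e in edges)))

        def emit(src_id: int, entry_index: int) -> None:
            pending.setdefault((src_core, src_id), []).append(
                (offset, entry_index))

        def add_entry(entry: AxonInEntry) -> int:
            dst_tab.entries.append(entry)
            return len(dst_tab.entries) - 1

        for sig in sorted(groups):
            dsts, width = sig
            members = sorted(groups[sig])
            singles: List[Tuple[int, Tuple[int, ...]]] = []
            if len(dsts) == n_dst:
                # 1*: every source gets a full sequential-weight entry
                for src_id, weights in members:
                    block = dst_tab.add_block(weights, width)
                    idx = add_entry(AxonInEntry("full", width, block))
                    emit(src_id, idx)
                continue
            if len(members) > 1:
                if len(dsts) == 1 and len({w for _, w in members}) == 1:
                    # 2*: shared single target, shared weight
                    block = dst_tab.add_block(members[0][1], width)
                    idx = add_entry(AxonInEntry(
                        "shared", width, block, index=dsts[0]))
                    for src_id, _ in members:
                        emit(src_id, idx)
                    continue
                # 3*: one index list, weight rows ordered by source rank;
                # a source whose already-assigned rank conflicts is
                # demoted to a private entry
                kept: List[Tuple[int, Tuple[int, ...]]] = []
                for src_id, weights in members:
                    rank = assigned_rank.get((src_core, src_id))
                    if rank is None or rank == len(kept):
                        kept.append((src_id, weights))
                    else:
                        singles.append((src_id, weights))
                if len(kept) > 1:
                    flat: List[int] = []
                    for _, weights in kept:
                        flat.extend(weights)
                    block = dst_tab.add_block(flat, width)
                    idx = add_entry(AxonInEntry(
                        "group", width, block, indexes=dsts, rows=len(kept)))
                    for rank, (src_id, _) in enumerate(kept):
                        assigned_rank[(src_core, src_id)] = rank
                        emit(src_id, idx)
                else:
                    singles.extend(kept)
            else:
                singles = list(members)

            for src_id, weights in singles:
                if len(dsts) == 1:
                    block = dst_tab.add_block(weights, width)
                    idx = add_entry(AxonInEntry(
                        "point", width, block, index=dsts[0]))
                elif _contiguous(dsts):
                    # 4*: first index + count + sequential weights
                    block = dst_tab.add_block(weights, width)
                    idx = add_entry(AxonInEntry(
                        "range", width, block, index=dsts[0],
                        count=len(dsts)))
                else:
                    block = dst_tab.add_block(weights, width)
                    idx = add_entry(AxonInEntry(
                        "group", width, block, indexes=dsts, rows=1))
                emit(src_id, idx)

    # build axon-out chains (identical chains shared: case 2#)
    for (src_core, src_id), targets in sorted(pending.items()):
        out_tab = core_tables(src_core).axon_out
        rank = assigned_rank.get((src_core, src_id), 0)
        out_tab.set_chain(src_id, targets, rank)

    # physical word budgets
    for core, ct in tables.items():
        g = geo(core)
        if ct.axon_in.words() > g.D1:
            raise CapacityError(
                f"core {core}: axon-in footprint {ct.axon_in.words()} words "
                f"exceeds depth D1={g.D1}")
        if ct.axon_out.words() > g.D2:
            raise CapacityError(
                f"core {core}: axon-out footprint {ct.axon_out.words()} "
                f"words exceeds depth D2={g.D2}")
    return tables


def expand_tables(tables: Dict[Coord, CoreTables]) -> ConnectionList:
    """Exact inverse of :func:`build_tables`: recover the full edge set."""
    edges: List[Edge] = []
    for src_core, ct in sorted(tables.items()):
        for neuron in sorted(ct.axon_out.linkers):
            for offset, idx, src_index in lookup_axon_out(ct.axon_out, neuron):
                dst_core = (src_core[0] + offset[0], src_core[1] + offset[1])
                if dst_core not in tables:
                    raise StructuralError(
                        f"chain of {src_core}:{neuron} points at missing "
                        f"core {dst_core}")
                dst_in = tables[dst_core].axon_in
                entry = dst_in.entries[idx] if idx < len(dst_in.entries) else None
                if entry is None:
                    raise StructuralError(
                        f"dangling linker {src_core}:{neuron} -> {idx}")
                for post_id, weight in resolve_axon_in(dst_in, idx, src_index):
                    edges.append(Edge(src_core, neuron, dst_core, post_id,
                                      weight, entry.width))
    return ConnectionList(edges)


def spike_targets(tables: Dict[Coord, CoreTables], core: Coord,
                  neuron: int) -> List[Tuple[Coord, int, int]]:
    """All (target core, target neuron, raw weight) reached by one spike."""
    ct = tables[core]
    out = []
    for offset, idx, src_index in lookup_axon_out(ct.axon_out, neuron):
        dst_core = (core[0] + offset[0], core[1] + offset[1])
        dst_in = tables[dst_core].axon_in
        for post_id, weight in resolve_axon_in(dst_in, idx, src_index):
            out.append((dst_core, post_id, weight))
    return out


# ---------------------------------------------------------------------------
# Memory accounting across mechanisms
# ---------------------------------------------------------------------------

BASELINE_MECHANISMS = ("crossbar", "normal index", "synaptic expansion",
                       "population index", "darwin3")


def baseline_memory(conns: ConnectionList, mechanism: str,
                    geometry: Optional[CoreGeometry] = None) -> int:
    """Weight-memory words needed to store the connections under a given
    representation mechanism (one 64-bit word granularity).

    crossbar            dense R x C array per active target core
                        (R = D1 axon rows, C = N neurons);
    normal index        one entry word per synapse on each side;
    synaptic expansion  as normal index (capacity, not footprint, is
                        what its core-merging extends);
    population index    one full N-weight row per (source, target core)
                        link plus one axon-out word per link;
    darwin3             the compressed axon tables built here.
    """
    mech = mechanism.lower()
    g = geometry or CoreGeometry()
    edges = conns.edges
    if mech == "crossbar":
        active = {e.post_core for e in edges}
        width = max((e.width for e in edges), default=16)
        per_core = -(-(g.D1 * g.N * width) // WORD_BITS)
        return len(active) * per_core
    if mech in ("normal index", "synaptic expansion"):
        return 2 * len(edges)
    if mech == "population index":
        links = {(e.pre_core, e.pre_id, e.post_core) for e in edges}
        width = max((e.width for e in edges), default=16)
        row_words = -(-(g.N * width) // WORD_BITS)
        return len(links) * (row_words + 1)
    if mech == "darwin3":
        tables = build_tables(conns, default_geometry=g)
        return sum(ct.axon_in.words() + ct.axon_out.entry_words()
                   + len(ct.axon_out.linkers)
                   for ct in tables.values())
    raise ValueError(f"unknown mechanism {mechanism!r}; expected one of "
                     f"{BASELINE_MECHANISMS}")


# ---------------------------------------------------------------------------
# Topology mappers
# ---------------------------------------------------------------------------

def map_conv_layer(in_channels: int, out_channels: int, kernel: int,
                   input_size: int, stride: int = 1,
                   weights: Optional[Sequence[Sequence]] = None,
                   pre_core: Coord = (1, 0), post_core: Coord = (2, 0),
                   width: int = 8) -> ConnectionList:
    """Edge list of a 2-D convolutional layer (valid padding), laid out
    so that the shared kernel becomes shared weight rows in the tables.

    Input neuron ids are ``ci*H*W + y*W + x``; output ids are
    ``co*H'*W' + oy*W' + ox``.  ``weights[co][ci][ky][kx]`` defaults to a
    deterministic small-integer kernel.
    """
    H = W = input_size
    out_size = (input_size - kernel) // stride + 1
    if out_size < 1:
        raise ValueError(
            f"kernel {kernel} does not fit input {input_size} at "
            f"stride {stride}")

    def kweight(co: int, ci: int, ky: int, kx: int) -> int:
        if weights is not None:
            return int(weights[co][ci][ky][kx])
        lo = -(1 << (width - 1))
        span = (1 << width) - 1
        return lo + (co * 31 + ci * 17 + ky * 5 + kx * 3) % span

    edges = []
    for co in range(out_channels):
        for oy in range(out_size):
            for ox in range(out_size):
                post = co * out_size * out_size + oy * out_size + ox
                for ci in range(in_channels):
                    for ky in range(kernel):
                        for kx in range(kernel):
                            iy, ix = oy * stride + ky, ox * stride + kx
                            pre = ci * H * W + iy * W + ix
                            edges.append(Edge(pre_core, pre, post_core, post,
                                              kweight(co, ci, ky, kx), width))
    return ConnectionList(edges)
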