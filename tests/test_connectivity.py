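"""Compressed connectivity codec: cases, round trips, capacity, memory."""

import io

import numpy as np
import pytest

from darwinsim.connectivity import (
    CapacityError,
    ConnectionList,
    CoreGeometry,
    Edge,
    StructuralError,
    baseline_memory,
    build_tables,
    expand_tables,
    lookup_axon_out,
    map_conv_layer,
    max_fan_in,
    max_fan_out,
    resolve_axon_in,
    spike_targets,
)
from darwinsim.fixtures import random_network, small_geometry

A, B = (1, 0), (2, 0)


def _edges(pairs, width=16):
    return ConnectionList(
        [Edge(A, p, B, q, w, width) for p, q, w in pairs])


# -- capacity formulas -------------------------------------------------------

def test_fan_in_formula_values():
    assert max_fan_in(2, 4096) == 4096
    assert max_fan_in(1, 4096) == 0
    assert max_fan_in(65537, 4096) == 268435456   # 256 * 2**20


def test_fan_out_formula_values():
    assert max_fan_out(4096, 4096) == 0
    assert max_fan_out(16384, 4096) == 50331648   # 48 * 2**20
    with pytest.raises(ValueError):
        max_fan_out(10, 4096)


def test_small_instance_packing_matches_formula():
    """At N<=4 with 16-bit weights every full entry is one word, so the
    (D1-1)*N bound is exactly achievable and one edge more overflows."""
    geo = CoreGeometry(D1=3, D2=12, N=4)
    # two sources, each reaching all 4 neurons: 8 = (3-1)*4 synapses
    full = ConnectionList(
        [Edge(A, s, B, t, s + t, 16) for s in (0, 1) for t in range(4)])
    tables = build_tables(full, {A: geo, B: geo})
    assert expand_tables(tables) == full
    assert tables[B].axon_in.words() <= geo.D1
    over = ConnectionList(list(full) + [Edge(A, 2, B, 0, 9, 16)])
    with pytest.raises(CapacityError):
        build_tables(over, {A: geo, B: geo})


def test_fan_out_boundary_small_instance():
    geo = CoreGeometry(D1=64, D2=4, N=4)   # D2 == N: zero fan-out budget
    single = _edges([(0, 0, 1)])
    with pytest.raises(CapacityError, match="fan-out"):
        build_tables(single, {A: geo, B: small_geometry(4)})


# -- compression cases -------------------------------------------------------

def test_full_core_broadcast_uses_one_sequential_entry():
    n = 16
    geo = small_geometry(n)
    conns = ConnectionList([Edge(A, 3, B, t, t + 1, 16) for t in range(n)])
    tables = build_tables(conns, {A: geo, B: geo})
    entries = tables[B].axon_in.entries
    assert len(entries) == 1 and entries[0].kind == "full"
    assert resolve_axon_in(tables[B].axon_in, 0) == \
        [(t, t + 1) for t in range(n)]


def test_single_edge_gives_point_linker_and_entry():
    conns = _edges([(5, 9, -3)])
    tables = build_tables(conns, default_geometry=small_geometry())
    assert tables[B].axon_in.entries[0].kind == "point"
    assert lookup_axon_out(tables[A].axon_out, 5) == [((1, 0), 0, 0)]
    assert expand_tables(tables) == conns


def test_shared_weight_convergence_uses_single_entry():
    conns = _edges([(s, 7, 4) for s in (1, 2, 3)])
    tables = build_tables(conns, default_geometry=small_geometry())
    entries = tables[B].axon_in.entries
    assert len(entries) == 1 and entries[0].kind == "shared"
    assert resolve_axon_in(tables[B].axon_in, 0) == [(7, 4)]


def test_range_entry_expands_to_sequential_targets():
    conns = _edges([(2, 10 + j, j) for j in range(5)])
    tables = build_tables(conns, default_geometry=small_geometry())
    entry = tables[B].axon_in.entries[0]
    assert entry.kind == "range" and entry.index == 10 and entry.count == 5
    assert resolve_axon_in(tables[B].axon_in, 0) == \
        [(10 + j, j) for j in range(5)]


def test_group_entry_selects_weight_row_by_source_rank():
    targets = [4, 8, 15]
    conns = ConnectionList([Edge(A, s, B, t, 10 * s + t, 16)
                            for s in (1, 5) for t in targets])
    tables = build_tables(conns, default_geometry=small_geometry())
    entry = tables[B].axon_in.entries[0]
    assert entry.kind == "group" and entry.rows == 2
    assert resolve_axon_in(tables[B].axon_in, 0, 0) == \
        [(t, 10 + t) for t in targets]
    assert resolve_axon_in(tables[B].axon_in, 0, 1) == \
        [(t, 50 + t) for t in targets]
    # the two sources share one axon-out chain (case 2#)
    out = tables[A].axon_out
    assert len(out.chains) == 1
    assert out.linkers[1] == (0, 0) and out.linkers[5] == (0, 1)


def test_chain_last_flags_terminate_traversal():
    cores = [(2, 0), (3, 0), (1, 1)]
    conns = ConnectionList([Edge(A, 0, c, 1, 1, 16) for c in cores])
    tables = build_tables(conns, default_geometry=small_geometry())
    chain = tables[A].axon_out.chains[0]
    assert [e.last for e in chain] == [False, False, True]
    assert len(lookup_axon_out(tables[A].axon_out, 0)) == 3
    assert lookup_axon_out(tables[A].axon_out, 99) == []


def test_spike_targets_equal_expanded_edges_per_source():
    g = random_network(21, density=0.08)
    tables = build_tables(g, default_geometry=small_geometry())
    expanded = expand_tables(tables)
    for core, nid in {(e.pre_core, e.pre_id) for e in g}:
        want = sorted((e.post_core, e.post_id, e.weight)
                      for e in expanded
                      if (e.pre_core, e.pre_id) == (core, nid))
        got = sorted(spike_targets(tables, core, nid))
        assert got == want


def test_dangling_linker_raises_structural_error():
    conns = _edges([(0, 0, 1)])
    tables = build_tables(conns, default_geometry=small_geometry())
    with pytest.raises(StructuralError):
        resolve_axon_in(tables[B].axon_in, 5)


# -- round-trip property -----------------------------------------------------

@pytest.mark.parametrize("seed", range(30))
def test_roundtrip_on_random_graphs(seed):
    rng = np.random.default_rng(seed)
    g = random_network(seed, density=float(rng.uniform(0.0, 0.15)),
                       weight_widths=(4, 8, 16))
    tables = build_tables(g, default_geometry=small_geometry())
    assert expand_tables(tables) == g


def test_empty_tables_expand_to_empty_list():
    assert expand_tables(build_tables(ConnectionList())) == ConnectionList()


# -- memory accounting -------------------------------------------------------

def test_crossbar_cost_independent_of_edge_count():
    geo = small_geometry(16, D1=64)
    one = baseline_memory(_edges([(0, 0, 1)]), "crossbar", geo)
    many = baseline_memory(_edges([(s, t, 1) for s in range(4)
                                   for t in range(4)]), "crossbar", geo)
    assert one == many > 0


def test_compressed_beats_flat_index_on_shared_topologies():
    n = 32
    geo = small_geometry(n, D1=1 << 14)
    # all-to-all with a shared weight: strongly compressible
    conns = ConnectionList([Edge(A, s, B, t, 5, 8)
                            for s in range(n) for t in range(n)])
    darwin = baseline_memory(conns, "darwin3", geo)
    flat = baseline_memory(conns, "normal index", geo)
    assert darwin < flat


def test_conv_layer_words_near_kernel_parameter_count():
    conns = map_conv_layer(1, 2, 3, 6, width=8)
    geo = small_geometry(neurons_per_core=64, D1=1 << 14)
    tables = build_tables(conns, default_geometry=geo)
    assert expand_tables(tables) == conns
    # shared kernel rows are pooled: weight storage stays near the kernel
    # parameter count while indexes dominate the footprint
    pool = tables[(2, 0)].axon_in.pool
    distinct_weights = len({w for blk in pool for w in blk})
    assert distinct_weights <= 2 * 3 * 3
    assert baseline_memory(conns, "darwin3", geo) < \
        baseline_memory(conns, "normal index", geo)


def test_conv_examples():
    ident = map_conv_layer(1, 1, 1, 4)
    assert len(ident) == 16            # 1x1 kernel: one edge per pixel
    conns = map_conv_layer(1, 1, 3, 5)
    # every interior output sees all 9 kernel weights
    per_post = {}
    for e in conns:
        per_post.setdefault(e.post_id, []).append(e.weight)
    assert all(len(v) == 9 for v in per_post.values())
    with pytest.raises(ValueError):
        map_conv_layer(1, 1, 7, 5)


def test_unknown_mechanism_rejected():
    with pytest.raises(ValueError, match="unknown mechanism"):
        baseline_memory(ConnectionList(), "quantum")


# -- I/O ---------------------------------------------------------------------

def test_connection_list_csv_roundtrip():
    g = random_network(4, density=0.05, weight_widths=(8, 16))
    buf = io.StringIO()
    g.to_csv(buf)
    buf.seek(0)
    assert ConnectionList.from_csv(buf) == g


def test_duplicate_edges_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        ConnectionList([Edge(A, 0, B, 0, 1, 16), Edge(A, 0, B, 0, 2, 16)])


def test_generator_covers_every_compression_case():
    g = random_network(0, density=0.03)
    tables = build_tables(g, default_geometry=small_geometry())
    kinds = {e.kind for ct in tables.values() for e in ct.axon_in.entries}
    assert {"full", "shared", "group", "range", "point"} <= kinds
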