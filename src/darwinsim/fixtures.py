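"""Reproducible synthetic-network generators for tests and reports.

The random generator deliberately mixes connection motifs so that every
compression case of the connectivity codec (full 1*, shared 2*, group
3*, range 4* and point entries) appears in generated graphs when the
corresponding flags are enabled.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .connectivity import ConnectionList, CoreGeometry, Edge

Coord = Tuple[int, int]


def _rand_weight(rng: np.random.Generator, width: int) -> int:
    lo = -(1 << (width - 1))
    hi = (1 << (width - 1)) - 1
    return int(rng.integers(lo, hi + 1))


def random_network(seed: int,
                   cores: Sequence[Coord] = ((1, 0), (2, 0), (0, 1)),
                   neurons_per_core: int = 32,
                   density: float = 0.05,
                   weight_widths: Sequence[int] = (16,),
                   include_motifs: bool = True) -> ConnectionList:
    """Random multi-core connection list.

    ``density`` controls the random point-to-point part; with
    ``include_motifs`` the graph additionally contains one full-core
    broadcast (1*), one shared-weight convergence (2*), one
    group-to-group block (3*) and one contiguous-range fan-out (4*).
    """
    rng = np.random.default_rng(seed)
    cores = [tuple(c) for c in cores]
    n = neurons_per_core
    edges: Dict[Tuple, Edge] = {}

    def put(e: Edge) -> None:
        edges.setdefault((e.pre_core, e.pre_id, e.post_core, e.post_id), e)

    # the random point-to-point part stays in the lower id half so the
    # structured motifs below keep their clean per-source signatures
    half = n // 2 if include_motifs else n
    if density > 0 and half > 0:
        for pre_core in cores:
            for post_core in cores:
                mask = rng.random((half, half)) < density
                width = int(rng.choice(weight_widths))
                for pre_id, post_id in zip(*np.nonzero(mask)):
                    put(Edge(pre_core, int(pre_id), post_core, int(post_id),
                             _rand_weight(rng, width), width))

    if include_motifs and len(cores) >= 2 and n - half >= 16:
        width = int(max(weight_widths))
        a, b = cores[0], cores[1]
        hi = list(range(half, n))   # ids reserved for the motifs, disjoint
        # 1*: one source reaches every neuron of core b
        for post in range(n):
            put(Edge(a, hi[0], b, post, _rand_weight(rng, width), width))
        # 2*: several sources converge on one target with one weight
        wshared = _rand_weight(rng, width)
        for pre in hi[1:5]:
            put(Edge(b, pre, a, hi[5], wshared, width))
        # 3*: a source group projects onto a common target group
        for s in hi[6:9]:
            for t in hi[9:13]:
                put(Edge(a, s, b, t, _rand_weight(rng, width), width))
        # 4*: one source reaches a contiguous target range
        for j in range(4):
            put(Edge(b, hi[13], a, hi[6] + j, _rand_weight(rng, width),
                     width))
    return ConnectionList(edges.values())


def random_network_generator(seed: int, cores=((1, 0), (2, 0)),
                             density: float = 0.05,
                             weight_widths: Sequence[int] = (16,),
                             neurons_per_core: int = 32,
                             include_motifs: bool = True) -> ConnectionList:
    """Alias with the argument order (seed, cores, density, widths)."""
    return random_network(seed, cores, neurons_per_core, density,
                          weight_widths, include_motifs)


def small_geometry(neurons_per_core: int = 32, D1: int = 4096,
                  D2: Optional[int] = None) -> CoreGeometry:
    """A small core geometry convenient for desk-scale fixtures."""
    return CoreGeometry(D1=D1, D2=D2 or (neurons_per_core + 4096),
                        N=neurons_per_core)
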