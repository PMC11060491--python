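"""Code-density and memory-usage reporting."""

from __future__ import annotations

from typing import Dict, Mapping, Optional, Union

import pandas as pd

from .connectivity import (
    BASELINE_MECHANISMS,
    ConnectionList,
    CoreGeometry,
    baseline_memory,
)
from .isa.asm import Program, assemble


def code_density_report(programs: Mapping[str, Union[Program, str]],
                        baseline_counts: Optional[Mapping[str, int]] = None
                        ) -> pd.DataFrame:
    """Instruction-word counts per model program, with optional density
    ratios against user-supplied baseline instruction counts (e.g. the
    same models compiled for a general-purpose ISA)."""
    rows = []
    for name, prog in programs.items():
        if isinstance(prog, str):
            prog = assemble(prog)
        count = len(prog)
        row = {"model": name, "instructions": count}
        if baseline_counts and name in baseline_counts:
            base = baseline_counts[name]
            row["baseline"] = base
            row["density_gain"] = round(base / count, 2) if count else None
        rows.append(row)
    return pd.DataFrame(rows)


def memory_report(conns: ConnectionList,
                  geometry: Optional[CoreGeometry] = None) -> pd.DataFrame:
    """Word footprint of a connection list under every storage mechanism."""
    rows = []
    compressed = baseline_memory(conns, "darwin3", geometry)
    for mech in BASELINE_MECHANISMS:
        words = baseline_memory(conns, mech, geometry)
        rows.append({"mechanism": mech, "words": words,
                     "ratio_vs_darwin3": round(words / compressed, 2)
                     if compressed else None})
    return pd.DataFrame(rows)
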