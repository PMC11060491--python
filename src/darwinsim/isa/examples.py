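"""Published assembly listings for widely used neuron/synapse/learning models.

These are the canonical code-density reference listings for the
architecture, reproduced in the source format the assembler accepts (one
instruction per line).  The hex operands are kept verbatim as
assembler/decoder round-trip fixtures; executable model programs with
fully specified semantics are built in :mod:`darwinsim.programs` instead.
"""

MODEL_LISTINGS = {
    "LIF": (
        "UPTVM 0xD\n"
        "GSPRS 0xA\n"
    ),
    "QIF": (
        "UPTTS 0x021\n"
        "MOV P0, RT0\n"
        "UPTVM 0xD\n"
        "GSPRS 0xA\n"
    ),
    "ExpIF": (
        "UPTTS 0x061\n"
        "EXP RT1 RT0\n"
        "UPTTS 0x48A\n"
        "MOV C0 RT2\n"
        "UPTVM 0xD\n"
        "GSPRS 0xA\n"
    ),
    "Izhikevich": (
        "UPTTS 0x143\n"
        "MOV P0, RT0\n"
        "UPTIS 0x38\n"
        "UPTVM 0x0F\n"
        "GSPRS 0xE\n"
    ),
    "Basic STDP": (
        "UPTLS 0x20\n"
        "UPTLS 0x08\n"
        "UPTWT 0x108\n"
        "UPTWT 0x260\n"
    ),
    "Triplet STDP": (
        "UPTLS 0x20\n"
        "UPTLS 0x08\n"
        "UPTLS 0x04\n"
        "UPTWT 0x10C\n"
        "UPTWT 0x264\n"
        "UPTWT 0x454\n"
    ),
    "RSTDP": (
        "UPTLS 0x20\n"
        "UPTLS 0x08\n"
        "UPTLS 0x02\n"
        "UPTWT 0x10C\n"
        "UPTWT 0x264\n"
    ),
    "S-TP": (
        "LayerH: UPTTS 0x15A\n"
        "MOV LP0 RT0\n"
        "UPTWT 0xC0\n"
        "LayerO: UPTWT 0x228\n"
    ),
    "SDSP": (
        "UPTLS 0x20\n"
        "CMP RT0 S0\n"
        "JMP Keep\n"
        "CMP RT1 LS1\n"
        "JMP Keep\n"
        "CMP LS1 RT3\n"
        "JMP Keep\n"
        "CMP LS1 RT2\n"
        "JMP UP\n"
        "SUB W RT4\n"
        "NOP\n"
        "Up: ADD W RT4\n"
        "Keep: NOP\n"
    ),
}

# Printed instruction counts, used by the code-density report tests.
MODEL_LISTING_LENGTHS = {name: sum(1 for ln in text.splitlines() if ln.strip())
                         for name, text in MODEL_LISTINGS.items()}
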