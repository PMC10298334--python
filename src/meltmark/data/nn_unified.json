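{
  "comment": "Unified nearest-neighbor DNA duplex parameters. dH in kcal/mol, dS in cal/(mol K), 1 M NaCl reference state. Stacks are keyed by the top-strand dinucleotide 5'->3'; complementary stacks share values.",
  "stacks": {
    "AA": [-7.9, -22.2],
    "TT": [-7.9, -22.2],
    "AT": [-7.2, -20.4],
    "TA": [-7.2, -21.3],
    "CA": [-8.5, -22.7],
    "TG": [-8.5, -22.7],
    "GT": [-8.4, -22.4],
    "AC": [-8.4, -22.4],
    "CT": [-7.8, -21.0],
    "AG": [-7.8, -21.0],
    "GA": [-8.2, -22.2],
    "TC": [-8.2, -22.2],
    "CG": [-10.6, -27.2],
    "GC": [-9.8, -24.4],
    "GG": [-8.0, -19.9],
    "CC": [-8.0, -19.9]
  },
  "initiation_terminal_GC": [0.1, -2.8],
  "initiation_terminal_AT": [2.3, 4.1],
  "gas_constant_cal": 1.987,
  "salt_entropy_coefficient": 0.368
}
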