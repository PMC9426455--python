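# End-to-end run over locally available coordinate files.
# Fetch inputs explicitly first, e.g.:  capsidphylo fetch 7NS0 --out-dir structures
# Core residue ranges (the jelly-roll fold span of each chain) must be supplied
# per structure in the core table; see examples/cores_example.tsv for the format.
structures:
  - [structures/7ns0.cif, A, CtenDNAV_II]
  # - [structures/xxxx.cif, A, SomeOtherVirus]
mode: core            # or full_length
core_table: examples/cores_example.tsv
clades:
  clade1: [CtenDNAV_II]   # extend with the ssRNA-virus labels under test
output_dir: runs/core_mode
seed: 0
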