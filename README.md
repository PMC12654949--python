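# knotlayers

Decompose the base pairs of an RNA 3D structure into pseudoknot-free layers
and render the result as viewer coloring scripts (PyMOL / classic Chimera),
extended dot-bracket strings, and corpus statistics.

## How it works

1. **Pair input** — read a structure (PDB or mmCIF) and obtain base pairs from
   one of three sources:
   * a pre-computed **RNAView** base-pair text output,
   * a pre-computed **DSSR** JSON output,
   * the **built-in geometric detector** (canonical pairs only: identities
     A–U / G–C / G–U with WC-edge N···N ≤ 3.2 Å and C1′–C1′ in [9.8, 11.0] Å,
     sequence separation > 2). No external binary is ever invoked.
2. **Selection** — keep intra-chain pairs of the requested chain; by default
   only canonical pairs (Watson–Crick A–U / G–C and wobble G–U in cis-WC
   geometry), or everything with `--include-all`.
3. **Layering** — repeatedly extract a maximum-cardinality non-crossing,
   one-pair-per-position subset with a Nussinov-style dynamic program
   (O(n³) time / O(n²) space per pass) until no pairs remain. Layer 0 is the
   core; each further layer is a pseudoknot / non-nested layer. The greedy
   scheme does not guarantee the minimum number of layers (by design).
4. **Rendering** — color unpaired residues white, the core gray, and layers
   1, 2, 3, … red, blue, green, … (palette configurable, cycling); emit
   per-layer PyMOL selections; optionally write the extended dot-bracket
   string (`()`, `[]`, `{}`, `<>`, then `Aa`, `Bb`, …).

## CLI

```sh
# built-in detector, PyMOL script
knotlayers visualize -i structure.cif -o coloring.pml -a builtin -c A -f pymol

# pre-computed annotator output (RNAView text or DSSR JSON), Chimera dialect
knotlayers visualize -i structure.pdb -o coloring.cmd \
    -a RNAView --annotation structure.pdb.out -c A -f chimera

# keep non-canonical pairs, also write dot-bracket
knotlayers visualize -i structure.cif -o out.pml --include-all --dotbracket db.txt

# corpus statistics (layer-count histogram, per-layer canonical fractions)
knotlayers stats --synthetic 100 --seed 1 --include-all --out-prefix run1
knotlayers stats --manifest chains.txt   # lines: <structure path> <chain id>
```

Flags `-i/-o/-a/-c/-f` select input, output, annotator, chain, and script
dialect; `--config FILE` supplies `key=value` defaults (flags win). Exit
codes: 0 success, 2 usage, 3 input error, 4 format error, 5 consistency
error. A chain with zero pairs yields a warning and an unpaired-only script.

## Synthetic fixtures

`knotlayers.synthdata` builds ground-truthed test instances: mutually
interleaved stems with known layering (`gen_planted_pairs`), schematic
mmCIF/PDB coordinate files that the built-in detector resolves exactly
(`gen_helix_mmcif` / `gen_helix_pdb`), RNAView-/DSSR-style annotation text
(`gen_rnaview_text` / `gen_dssr_json`), and seeded corpora (`gen_corpus`).

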