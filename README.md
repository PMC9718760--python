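# thiogag

Modelling toolkit for thio-glycosidic (S-linked) heparosan / heparan-sulfate
analogs:

- **glycan_model** — glycan chain representation (residues, O/S linkages,
  sulfation and other modifications, aglycones), elemental compositions,
  monoisotopic `[M-H]-` mass prediction, enzyme cleavage rules (heparanase
  hydrolysis vs heparin-lyase beta-elimination) and AMAC reductive-amination
  labeling of disaccharide fragments.
- **ring_pucker** — Cremer-Pople puckering coordinates (Q, theta, phi) of
  six-membered rings, the 38 canonical pyranose conformers with
  nearest-reference classification, inverse (canonical-ring) construction,
  sinusoidal equal-area projection, and per-residue conformer frequency
  tables over ensembles.
- **chain_geometry** — end-to-end distances (reducing O1 to the non-reducing
  position-4 heteroatom), per-linkage C-X bond lengths and C-X-C angles,
  histogram tables, contour-length bounds, and trajectory bookkeeping
  (frame counts, retained durations).
- **conformer_sampler** — synthetic-ensemble generator: per-ring conformer
  mixtures, Boltzmann-sampled harmonic linkage geometry
  (`E = K (x - x0)^2`, variance `kB*T / 2K`), von Mises glycosidic torsions,
  hard-sphere clash filtering, bit-reproducible from a seed.
- **frames / pipeline / cli** — multi-MODEL PDB and XYZ frame I/O, YAML/JSON
  run configuration, and the umbrella CLI.

## CLI

```sh
# composition + exact/nominal [M-H]- mass of a chain
thiogag mass "GlcNAc-O-GlcA-O-GlcNAc-O-GlcA-O-[C2H4-amido-benzaldehyde]"

# enzymatic digestion with AMAC-labeled fragment masses
thiogag digest "GlcA-S-GlcNAc-O-GlcA-S-GlcNAc" --enzyme lyase --amac

# generate a synthetic ensemble (multi-MODEL PDB + provenance JSON)
thiogag build-ensemble --chain preset:heparosan_deca_hemiA \
    --frames 1000 --seed 42 --out ensemble.pdb

# puckering / geometry analysis of a trajectory
thiogag pucker ensemble.pdb --residues 5,6 --out pucker.csv --summary freq.csv
thiogag geometry ensemble.pdb --out geometry.csv --histogram hist.csv

# full pipeline from a config file; reruns are byte-identical
thiogag run config.yaml

# built-in checks (38-conformer roundtrip, reference masses)
thiogag selftest
```

Chain grammar: residue tokens (`GlcA`, `GlcNAc`, `GlcN`, `GlcNS`, `dUA`,
`4SH-GlcNAc`) joined by `-O-` / `-S-`, with optional `@mods` suffixes
(`4S` thio, `NS`, `2S`, `6S` sulfo, `unsat`, `NAc`) and an optional bracketed
reducing-end aglycone (`-O-[C2H4-amido-benzaldehyde]`, or `[name:FORMULA]`).

Minimal pipeline config:

```yaml
seed: 42          # required
n_frames: 2000
bin_width: 0.5
output_dir: out
# chains:        # defaults to O-linked vs hemi-A S-linked decasaccharides
#   o_link: preset:heparosan_deca_O
#   s_link: preset:heparosan_deca_hemiA
# linkage_params: {S: {r0: 1.8392, k_bond: 215.9, theta0: 99.24, k_angle: 60.2}}
# torsions: {S: {phi_kappa: 3.0}}
# mixtures: {hexosamine: {1C4: 0.6, 4C1: 0.4}, uronic: {4C1: 1.0}}
```

## Conventions

- Chains are ordered non-reducing to reducing end; residues are numbered
  from 1 at the non-reducing end.
- Predicted masses are monoisotopic `[M-H]-` (proton-mass subtraction);
  nominal m/z is round-half-away-from-zero.
- Ring atom order is O5, C1, C2, C3, C4, C5; the puckering convention is
  calibrated (and asserted at import) so an ideal 4C1 chair gives theta = 0
  and the O,3B boat gives (theta, phi) = (90, 0).
- Coordinates are Angstrom everywhere; XYZ input may be flagged as nm.
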