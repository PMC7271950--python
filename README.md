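# embuild

De novo protein model building into cryo-EM density maps: likelihood-based
Cα tracing, sequence docking by side-chain density classification, and
iterative build cycles selected by average Fourier shell correlation.

Cryo-EM reconstructions at better than ~4 Å resolution show enough detail
to trace a protein's main chain directly from density, but the maps are
noisy, are not on an absolute density scale, and rarely resolve individual
residues unambiguously. `embuild` addresses this with fragment-likelihood
targets: from a reference map/model pair it learns, for every offset d_i in
a sphere around a residue centre, the mean μ_i and variance σ_i² of the
reference density, and scores a candidate placement (x, R) of that motif in
the work map by

    llk(x, R) = −Σ_i ( ρ(x + R·d_i) − μ_i )² / (2 σ_i²).

A 4 Å sphere centred on Cα locates and extends main chain; 5.5 Å spheres
centred on Cβ, one per amino-acid type, classify side chains so the known
sequences can be docked onto the traced fragments. Two adaptations matter
for EM maps: a *correlation* scoring mode that re-fits the map's scale and
offset before evaluating the likelihood (maps are not on the e/Å³ scale),
and a *fast* seed search that finds short helix- and strand-like motifs
with a scale-free correlation score. The pipeline iterates build cycles,
carrying each model into the next cycle, and reports the cycle whose model
best explains the map by FSC_average (the shell-count-weighted mean Fourier
shell correlation between the map and a rendering of the model).

Everything runs from synthetic fixtures with known ground truth — a
generator for ideal-geometry models, simulated maps and masks is part of
the package — so no external data is needed to build, test, or evaluate.
See `docs/methods.md` for the model, parameter choices and limitations.

## Worked example

Generate a 20-residue helix fixture (map, model, sequence, mask) and build
into it:

```sh
embuild-fixture --fold helix --nres 20 --resolution 3 --seed 2 --out fx
embuild --mapin fx.mrc --seqin fx.fasta --resolution 3 --cycles 1 --out run1
```

which prints

```
no reference given; simulating the built-in synthetic reference
cycle 1: 22 residues in 1 fragments, 20 sequenced, FSC_average 0.172 -> run1_cycle1.pdb
best cycle: 1 (written to run1_cycle1.pdb)
```

The tool traced one fragment of 22 residues (the 20-residue helix plus a
little overbuild at the termini), docked the sequence onto 20 of them, and
wrote the model plus a `run1_stats.json` with per-cycle counts and
FSC_average. With several cycles, `run1_cycle{i}.pdb` is written per cycle
and the best cycle is chosen by FSC_average.

A reference map/model pair of your own can be supplied with
`--refmap/--refmodel`, or simulated from any coordinate model with
`--simulate-reference model.pdb`; sequences are standard FASTA, maps
MRC/CCP4 2014 volumes. `--known-structure "A:3.0"` preserves chain A of the
input model verbatim and keeps new chain 3 Å away from it;
`--nonprotein-radius 2` does the same for ligands.

Python API: the same stages are importable (`embuild.map_io`,
`embuild.reference_targets`, `embuild.search`, `embuild.build`,
`embuild.sequencing`, `embuild.pipeline`, `embuild.evaluation`,
`embuild.synthetic`); `embuild.pipeline.run_pipeline` is the one-call
entry point.

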