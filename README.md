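# parch

Per-residue hydropathy scoring from simulated-annealing water evaporation,
with quantification of how post-translational modifications (PTMs) reshape
local hydropathy.

## The problem

Whether a residue on a protein surface is hydrophobic or hydrophilic governs
solvation, packing and binding — and a phosphorylation, acetylation or
methylation can flip that character locally. The PARCH approach measures
hydropathy operationally: the protein is embedded in a thin explicit water
shell (thickness *d*<sub>shell</sub> = 0.415 nm) and heated linearly in the
NVT ensemble from 300 to 800 K at 1 K / 10 ps while the protein heavy atoms
and counter-ions are position-restrained. Hydrophilic residues hold their
contact waters (water oxygen within *d*<sub>water</sub> = 0.315 nm of a
residue heavy atom) to high temperature; hydrophobic residues shed them
early. Each residue gets a PARCH value

> PV = 10 · clamp( ⟨contacts⟩<sub>final window</sub> / ⟨contacts⟩<sub>initial window</sub>, 0, 1 ) ∈ [0, 10],

averaged over five replicate annealing runs (0 = hydrophobic, 10 =
hydrophilic). Comparing an unmodified and a modified variant gives
ΔPV = PV<sub>mod</sub> − PV<sub>unmod</sub> at the modification site and for
every residue whose heavy atoms come within 0.3 nm of it; |ΔPV| > 0.2 counts
as a real hydropathy change, and a paired Wilcoxon signed-rank test (exact
for ≤ 25 pairs) asks whether the neighborhood shifted significantly.

This package builds the annealing system geometry and engine inputs, scores
trajectories, and runs the ΔPV comparison. It does **not** run molecular
dynamics: annealing trajectories come from an external MD engine — or from
the built-in synthetic generator, which emulates water escape with an
analytic ground truth (expected PV = 10·h for prescribed hydropathy h), so
the whole stack is testable on a laptop.

## Worked example

End-to-end on synthetic data — ten pseudo-residues with hydropathies spanning
0.1–0.9, one residue perturbed by Δh = +0.4 to emulate a phosphorylation,
five replicates each:

```bash
$ parch all-synthetic --n-residues 6 --waters-per-residue 20 --n-frames 40 --out-dir clirun
INFO parch: d_shell = 0.415 nm
INFO parch: d_water = 0.315 nm
INFO parch: neighbor_cutoff = 0.3 nm
INFO parch: delta_threshold = +/-0.2 PV units
INFO parch: ramp 300 -> 800 K at 0.1 K/ps
site ΔPV = +2.83 (increase); report in clirun
```

`clirun/parch_unmod.tsv` holds the per-residue scores; the first rows:

```
chain  resnum  resname  PV_mean  PV_sd     n_rep  buried_flag
A      1       ALA      1.66154  0.590951  5      0
A      2       ALA      2.91538  0.52324   5      0
```

Residue 1 was prescribed hydropathy 0.1, residue 2 ≈ 0.26 — the recovered
means sit near 10·h as expected (at 20 waters/residue the binomial sampling
noise is visible in PV_sd; at the study conditions of 50 waters it shrinks
below 0.5). `clirun/report.json` contains the full ΔPV report for the
perturbed site: per-neighbor deltas and classes, the cumulative neighborhood
change, and the Wilcoxon verdict.

For real proteins the workflow is

```bash
parch build   --solvated protein_solv.pdb --replicates 5 --out-dir build/
# ... run the five annealing replicates in your MD engine using build/*.mdp ...
parch score   --structure build/system.gro --traj rep1.xtc ... --out parch_u.tsv
parch compare --unmod parch_u.tsv --mod parch_m.tsv \
              --structure unmod.pdb --mod-structure mod.pdb --out report.json
```

Modified residues are recognised by their three-letter codes (SEP/TPO/PTR
phospho, ALY acetyl, MLZ/MLY/NMM/AGM methyl) and paired with their canonical
parents by global sequence alignment, so numbering differences between the
two variants are handled automatically.

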