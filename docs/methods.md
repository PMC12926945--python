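# Methods

## The measurement

The package scores residue hydropathy by water retention under heating. A
protein is wrapped in a thin explicit water shell and heated linearly in the
NVT ensemble; the per-residue count of contact waters — distinct water
molecules whose oxygen lies within *d*<sub>water</sub> of any heavy atom of
the residue, each water counted at most once per residue per frame — is
tracked along the ramp. The PARCH value reduces that evaporation profile to a
single number in [0, 10]:

    PV = 10 · clamp( mean(counts in final window) / mean(counts in initial window), 0, 1 )

with initial and final windows each covering a fraction (default 5 %) of the
frames. A residue whose initial window holds no water at all is buried; it is
reported as PV = 0 with a `buried_flag`, since a retention ratio is undefined
for it. PVs are averaged over replicate annealing runs (mean ± sample sd).

The retention-ratio reduction is implemented behind a pluggable
scoring-strategy interface; an alternative scorer based on the
half-evaporation temperature (`escape_temperature_scorer`) is provided for
robustness checks of scorer-independent conclusions. Counts are averaged over
frame windows, not temperature windows; with the uniform frame spacing the
schedules produce, the two coincide.

## Protocol parameters

| parameter | default | units | role |
|---|---|---|---|
| d_shell | 0.415 | nm | water-shell thickness; a water is retained iff its oxygen is within this distance of a protein heavy atom (inclusive) |
| restraint_k | 1×10⁴ | kJ mol⁻¹ nm⁻² | position restraint on protein heavy atoms and counter-ions |
| d_ion | 3.0 | nm | minimum counter-ion-to-protein distance |
| d_b | 3.0 | nm | ion–box boundary margin |
| min_tol | 1×10³ | kJ mol⁻¹ nm⁻¹ | steepest-descent minimisation tolerance (emitted to the engine template) |
| T_start → T_end | 300 → 800 | K | annealing ramp endpoints |
| rate | 0.1 | K ps⁻¹ | heating rate (1 K per 10 ps; 5000 ps ramp) |
| d_water | 0.315 | nm | water-contact cutoff, inclusive |
| neighbor_cutoff | 0.3 | nm | heavy-atom minimum distance defining a site's neighborhood |
| delta_threshold | 0.2 | PV units | \|ΔPV\| beyond which a residue's change counts as real |
| replicates | 5 | — | independent annealing runs averaged per residue |
| w_init, w_final | 0.05 | fraction | scoring-window sizes; no published value exists, 5 % keeps the windows inside the flat ends of the ramp while averaging enough frames to suppress counting noise |

The contact probe is the water oxygen and the target is the residue's heavy
atoms: the oxygen is the conventional locus of a water molecule and hydrogen
positions only add noise at these cutoffs. Modified residues are scored over
all their atoms, including the added phosphate/acetyl/methyl group.

## System construction

The shell is carved from a user-supplied pre-solvated, equilibrated snapshot
rather than synthesised, which keeps the package out of the solvation and
force-field business and matches the equilibrate-then-anneal workflow.
Bulk ions present in the snapshot are dropped along with bulk water: the
protocol places its own counter-ions, restrained, at controlled positions, so
inheriting free bulk ions would double-count charge and leave unrestrained
charges in vacuum.

Counter-ions are bare monovalent species (NA or CL) placed on
spherical-Fibonacci directions from the protein centroid — deterministic
given the seed — walking outward until the clearance to every protein heavy
atom is ≥ d_ion. The box is cubic with margin max(d_b, d_ion + 0.5 nm)
beyond the protein extent. Charge neutrality after placement is exact by
construction and verified exhaustively in tests.

The restraints apply to protein heavy atoms and counter-ions; the shell
waters are deliberately left free — the measurement *is* their evaporation.
The emitted inputs are a coordinate file, a plain-text restrained-serial
listing, and one key-value ramp template per replicate (seeded
`gen-seed = base_seed + replicate − 1`); running the dynamics is the user's
MD engine's job.

## ΔPV comparison

Residues of the unmodified and modified variants are paired by global
alignment of parent one-letter sequences per chain (match 1, mismatch 0,
gap −1), so a phosphoserine aligns as serine; alignment identity below 90 %
is refused. The neighborhood of a site is measured on the *unmodified*
structure, which makes the residue set identical for both states. Cumulative
neighborhood change defaults to the signed sum over neighbors with
|ΔPV| > 0.2 (`cumulative_mode="filtered"`); summing all neighbors is
available as `"all"`.

The Wilcoxon signed-rank test pairs the neighborhood residues' replicate-mean
PVs (the site itself excluded). Zero differences are dropped (classical
convention, not Pratt); tied |differences| get mid-ranks; W = min(W⁺, W⁻).
For n ≤ 25 effective pairs the two-sided p is exact: the full 2ⁿ signed-rank
null distribution is built by generating-function convolution (arithmetically
identical to enumerating every sign assignment, mid-rank ties included) and
p = P(min(W⁺, W⁻) ≤ W_obs). Above n = 25 a normal approximation with the
standard tie correction is used, without continuity correction. Significance
is declared at α = 0.05. No multiple-testing correction is applied across
sites or proteins — tests are reported per site.

## The synthetic generator

`synthetic_data` emulates the one property the scorer measures: waters
leaving residue contact shells at residue-dependent temperatures. Each
pseudo-residue is a single heavy atom with *m* water oxygens placed at
0.12–0.28 nm (safely inside the cutoff); residues sit ≥ 2 × displacement
radius apart so shells never interact. Under the default *persistent* escape
model each water stays for the whole ramp with probability h (the prescribed
hydropathy) and otherwise escapes at a temperature uniform on
(T_start, T_end), jumping radially to the displacement radius (1.5 nm) once
passed. The expected retention ratio is exactly h, so expected PV = 10·h — an
analytic ground truth. A *smooth* alternative (normal escape temperatures
centred at the ramp fraction h) exists for robustness tests of the
temperature-based scorer. Everything is deterministic in the seed; replicates
are derived as `seed + 1000·r`. Because the perturbed and unperturbed specs
share a seed, their persistent-water draws are coupled, which makes ΔPV
recovery exactly antisymmetric in Δh and lowers its variance.

What the generator does *not* emulate: real water dynamics, hydrogen bonding,
cooperative shell effects, buried residues, conformational change upon
modification, or any energetics. Passing the recovery tests shows the
counting, scoring, aggregation and comparison machinery is correct, not that
the annealing protocol itself resolves hydropathy on real proteins — that
evidence requires MD-generated trajectories.

### Statistical behavior of the recovery benchmark

Per replicate the retained-water count is Binomial(m, h), so at the study
conditions (m = 50, 5 replicates) the sd of the recovered PV is
10·√(h(1−h)/50)/√5 ≤ 0.32. Two small systematic terms exist: non-persistent
waters with escape temperatures inside the initial window deflate the
denominator, and those escaping only inside the final window inflate the
numerator; both scale with the window fraction (≤ ~0.2 PV units at 5 %
windows). The maximum error over 20 residues therefore fluctuates around the
0.5-unit recovery bound from seed to seed; the tests pin the study conditions
at the package default seed.

## Numerical choices

- All cutoffs are boundary-inclusive, with a 10⁻¹² nm tolerance against
  floating-point representation of exact boundary fixtures.
- Distances use k-d trees (scipy.spatial.cKDTree); every counting path has a
  brute-force all-pairs oracle in the test suite asserting exact integer
  agreement.
- Coordinates are stored in nm; PDB ångströms are divided by 10 on parse.
  Residue numbering follows the source file verbatim; internal keys are
  (chain_id, seq_number).
- Scoring windows round to frames via `max(1, round(w·n_frames))`.
- Degenerate inputs: all-zero Wilcoxon differences give p = 1 with a
  degenerate flag; an empty neighborhood gives a degenerate test rather than
  an error; an empty carved shell or unplaceable ion raises.

## Known limitations

- The PV normalisation implemented here is the retention ratio; laboratories
  using an evaporation-temperature normalisation can swap the scorer but the
  numerical PV scales will differ.
- Multi-frame PDB trajectories carry no time stamps; frame times are
  synthesised from the schedule's frame interval (or a caller-supplied dt).
- The modified-residue recognition table covers the common wwPDB codes
  (SEP, TPO, PTR, ALY, MLZ, MLY, NMM, AGM) and is config-extensible; exotic
  codes are skipped with a logged warning.
- `formal_net_charge` is neutral-pH formal-charge bookkeeping (it ignores
  termini and protonation microstates); supply `--net-charge` when the
  snapshot's true charge is known.
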