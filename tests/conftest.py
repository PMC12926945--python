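"""Shared fixtures: hand-written text fixtures and seeded synthetic systems.

Everything is generated programmatically at test time; the only verbatim
fixture is a minimal hand-written PDB whose contents the tests assert
line-by-line.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from parch import (AnnealingSchedule, Atom, Residue, Structure, SyntheticSpec,
                   aggregate_replicates, build_profiles,
                   generate_annealing_trajectory, generate_reference_system,
                   parch_from_profile)

# A minimal, hand-written single-residue PDB (5 atoms of an alanine backbone).
MINIMAL_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.761   6.834  -4.159  1.00  0.00           C
ATOM      4  O   ALA A   1       9.605   7.089  -4.458  1.00  0.00           O
ATOM      5  CB  ALA A   1      11.723   4.630  -4.663  1.00  0.00           C
END
"""

# Three residues and two waters; the water count and atom totals are asserted
# against an independent line-count oracle over the ATOM records.
TRIPEPTIDE_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.450   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   GLY A   1       1.300   2.400   0.000  1.00  0.00           O
ATOM      5  N   SER A   2       3.300   1.500   0.000  1.00  0.00           N
ATOM      6  CA  SER A   2       4.000   2.800   0.000  1.00  0.00           C
ATOM      7  CB  SER A   2       5.500   2.600   0.200  1.00  0.00           C
ATOM      8  OG  SER A   2       6.200   3.800   0.100  1.00  0.00           O
ATOM      9  C   SER A   2       3.500   3.700   1.100  1.00  0.00           C
ATOM     10  O   SER A   2       3.300   3.200   2.200  1.00  0.00           O
ATOM     11  N   LYS A   3       3.300   5.000   0.800  1.00  0.00           N
ATOM     12  CA  LYS A   3       2.800   6.000   1.800  1.00  0.00           C
ATOM     13  C   LYS A   3       1.300   6.000   1.900  1.00  0.00           C
ATOM     14  O   LYS A   3       0.600   5.500   1.000  1.00  0.00           O
HETATM   15  O   HOH W 101       8.000   3.000   0.000  1.00  0.00           O
HETATM   16  O   HOH W 102      12.000   8.000   5.000  1.00  0.00           O
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path


@pytest.fixture
def tripeptide_pdb(tmp_path):
    path = tmp_path / "tripeptide.pdb"
    path.write_text(TRIPEPTIDE_PDB)
    return path


def make_peptide_with_waters(n_residues: int = 3, n_waters: int = 50,
                             seed: int = 0, water_spread: float = 2.0,
                             resnames: list[str] | None = None) -> Structure:
    """A toy chain of single-atom residues plus waters scattered around it."""
    rng = np.random.default_rng(seed)
    residues = []
    serial = 0
    for i in range(n_residues):
        serial += 1
        name = resnames[i] if resnames else "ALA"
        residues.append(Residue(
            chain_id="A", seq_number=i + 1, name=name,
            atoms=[Atom(serial=serial, name="CA", element="C",
                        coordinates=np.array([0.4 * i, 0.0, 0.0]))]))
    for w in range(n_waters):
        serial += 1
        pos = rng.uniform(-water_spread, water_spread, size=3)
        pos[0] += 0.2 * n_residues
        residues.append(Residue(
            chain_id="W", seq_number=w + 1, name="HOH",
            atoms=[Atom(serial=serial, name="O", element="O", coordinates=pos)],
            is_solvent=True))
    return Structure(residues=residues)


def score_synthetic(spec: SyntheticSpec, n_replicates: int = 5,
                    n_frames: int = 100):
    """simulate → score for one spec; replicates re-seeded deterministically."""
    structure = None
    reps = []
    for r in range(n_replicates):
        rep_spec = dataclasses.replace(spec, seed=spec.seed + 1000 * r)
        structure, truth = generate_reference_system(rep_spec)
        traj = generate_annealing_trajectory(structure, truth, spec.schedule,
                                             n_frames)
        profiles = build_profiles(traj, structure, spec.schedule, spec.contact)
        reps.append({p.residue_key: parch_from_profile(p) for p in profiles})
    return structure, aggregate_replicates(reps)


def brute_force_contacts(frame: np.ndarray, structure: Structure,
                         residue_key, d_water: float) -> int:
    """Independent all-pairs oracle for the water-contact count."""
    res = structure.residue(residue_key)
    slices = structure.atom_slices()
    heavy = [frame[slices[res.key].start + i]
             for i, a in enumerate(res.atoms) if a.is_heavy]
    n = 0
    for wres in structure.water_residues:
        probe = wres.probe_oxygen()
        if probe is None:
            continue
        oidx = slices[wres.key].start + wres.atoms.index(probe)
        opos = frame[oidx]
        if any(np.linalg.norm(opos - h) <= d_water for h in heavy):
            n += 1
    return n
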