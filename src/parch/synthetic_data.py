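"""Synthetic annealing trajectories with analytic ground-truth hydropathy.

A contact-pattern generator, not a simulator of matter: each pseudo-residue
is a single heavy atom surrounded by ``m`` water oxygens inside the contact
cutoff. Every water is either *persistent* (stays for the whole ramp, with
probability h_i, the residue's prescribed hydropathy) or is assigned an
escape temperature uniform on (T_start, T_end); once the ramp passes that
temperature the water is displaced radially out of contact range. The
expected retention ratio therefore equals h_i exactly, so the expected PARCH
value is 10·h_i — an analytic ground truth against which the whole scoring
and comparison stack can be validated without an MD engine.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


import numpy as np

from .parch_scoring import AnnealingSchedule, ContactParams
from .structures_io import Atom, Residue, ResidueKey, Structure, Trajectory

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_reference_system",
    "generate_annealing_trajectory",
    "perturb_site",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Prescription for a synthetic annealing system.

    hydropathy h_i ∈ [0, 1] is the fraction of residue i's waters that never
    evaporate; expected PV is 10·h_i. Residues are spaced so no water can be
    shared or migrate into another residue's contact shell.
    """

    n_residues: int
    hydropathy: tuple[float, ...]
    waters_per_residue: int = 50
    displacement_radius: float = 1.5   # nm; escaped waters parked here
    seed: int = 1
    schedule: AnnealingSchedule = field(default_factory=AnnealingSchedule)
    contact: ContactParams = field(default_factory=ContactParams)
    escape_model: str = "persistent"   # or "smooth" (normal escape temps)

    def __post_init__(self) -> None:
        object.__setattr__(self, "hydropathy", tuple(float(h) for h in self.hydropathy))
        if self.n_residues < 1:
            raise ValueError("need at least one residue")
        if len(self.hydropathy) != self.n_residues:
            raise ValueError("hydropathy list length must equal n_residues")
        if any(not 0.0 <= h <= 1.0 for h in self.hydropathy):
            raise ValueError("hydropathy values must lie in [0, 1]")
        if self.waters_per_residue < 1:
            raise ValueError("need at least one water per residue")
        if self.displacement_radius <= self.contact.d_water:
            raise ValueError("displacement_radius must exceed the contact cutoff")


@dataclass
class GroundTruth:
    """What the generator prescribed: expected PVs and per-water escape temps."""

    expected_pv: np.ndarray          # 10·h_i per residue
    escape_temperatures: np.ndarray  # per water, K; inf = persistent
    water_owner: np.ndarray          # per water, residue index
    residue_keys: list[ResidueKey]
    water_keys: list[ResidueKey]
    displacement_radius: float

    def __post_init__(self) -> None:
        if np.any(self.expected_pv < 0) or np.any(self.expected_pv > 10):
            raise ValueError("expected PV out of [0, 10]")


def generate_reference_system(spec: SyntheticSpec) -> tuple[Structure, GroundTruth]:
    """Build the pseudo-protein + hydration waters and draw escape temperatures.

    Residues are single-heavy-atom pseudo-residues named with canonical codes,
    placed on a line at ≥ 2·displacement_radius spacing; each gets ``m`` water
    oxygens at radii safely inside the contact cutoff. Deterministic in
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.waters_per_residue
    spacing = 2.0 * spec.displacement_radius + 0.5
    sched = spec.schedule

    residues: list[Residue] = []
    serial = 0
    res_positions = []
    for i in range(spec.n_residues):
        serial += 1
        pos = np.array([i * spacing, 0.0, 0.0])
        res_positions.append(pos)
        residues.append(Residue(
            chain_id="A", seq_number=i + 1, name="ALA",
            atoms=[Atom(serial=serial, name="CA", element="C", coordinates=pos)]))

    # hydration waters: random directions, radii well inside d_water
    water_owner = []
    water_keys: list[ResidueKey] = []
    escape_T = []
    wseq = 0
    r_lo, r_hi = 0.12, min(0.28, spec.contact.d_water - 0.01)
    for i, pos in enumerate(res_positions):
        h = spec.hydropathy[i]
        dirs = rng.normal(size=(m, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        radii = rng.uniform(r_lo, r_hi, size=m)
        if spec.escape_model == "persistent":
            persistent = rng.random(m) < h
            temps = rng.uniform(sched.T_start, sched.T_end, size=m)
            temps[persistent] = np.inf
        elif spec.escape_model == "smooth":
            # escape temps normal around the ramp point where a fraction h remains
            center = sched.T_start + h * (sched.T_end - sched.T_start)
            temps = rng.normal(center, 0.08 * (sched.T_end - sched.T_start), size=m)
        else:
            raise ValueError(f"unknown escape model {spec.escape_model!r}")
        for j in range(m):
            wseq += 1
            serial += 1
            wpos = pos + dirs[j] * radii[j]
            residues.append(Residue(
                chain_id="W", seq_number=wseq, name="HOH",
                atoms=[Atom(serial=serial, name="O", element="O",
                            coordinates=wpos)],
                is_solvent=True))
            water_owner.append(i)
            water_keys.append(("W", wseq))
            escape_T.append(temps[j])

    structure = Structure(residues=residues)
    truth = GroundTruth(
        expected_pv=10.0 * np.asarray(spec.hydropathy),
        escape_temperatures=np.asarray(escape_T),
        water_owner=np.asarray(water_owner, dtype=int),
        residue_keys=[("A", i + 1) for i in range(spec.n_residues)],
        water_keys=water_keys,
        displacement_radius=spec.displacement_radius)
    return structure, truth


def generate_annealing_trajectory(structure: Structure, truth: GroundTruth,
                                  schedule: AnnealingSchedule = AnnealingSchedule(),
                                  n_frames: int = 100) -> Trajectory:
    """Play the escape model along the ramp: frame times uniform over the ramp;
    in each frame every water whose escape temperature has been passed sits
    parked at ``displacement_radius`` from its residue, the rest stay put."""
    if n_frames < 2:
        raise ValueError("need at least two frames")
    times = np.linspace(0.0, schedule.duration, n_frames)
    temps = schedule.T_start + schedule.rate * times

    base = structure.coordinates()
    slices = structure.atom_slices()
    res_pos = np.array([base[slices[k].start] for k in truth.residue_keys])
    water_idx = np.array([slices[k].start for k in truth.water_keys])
    owners = truth.water_owner
    wpos = base[water_idx]
    offsets = wpos - res_pos[owners]
    norms = np.linalg.norm(offsets, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    parked = res_pos[owners] + offsets / norms * truth.displacement_radius

    frames = np.repeat(base[None, :, :], n_frames, axis=0)
    for f in range(n_frames):
        gone = truth.escape_temperatures <= temps[f]
        frames[f, water_idx[gone]] = parked[gone]
    return Trajectory(frame_times=times, frames=frames)


def perturb_site(spec: SyntheticSpec, residue_index: int,
                 delta_h: float) -> SyntheticSpec:
    """Copy of the spec with one residue's hydropathy shifted by ``delta_h``.

    Emulates a post-translational modification changing local water affinity;
    all other residues and the seed are unchanged, so paired comparison is
    meaningful. Raises if the perturbed hydropathy leaves [0, 1].
    """
    if not 0 <= residue_index < spec.n_residues:
        raise IndexError(f"residue index {residue_index} out of range")
    new_h = spec.hydropathy[residue_index] + delta_h
    if not 0.0 <= new_h <= 1.0:
        raise ValueError(f"perturbed hydropathy {new_h:.3f} outside [0, 1]")
    hydro = list(spec.hydropathy)
    hydro[residue_index] = new_h
    return dataclasses.replace(spec, hydropathy=tuple(hydro))
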