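"""Annealing-system geometry: water shell, counter-ions, engine inputs.

The scoring protocol does not heat a fully solvated box: the protein is
embedded in a thin explicit water shell (thickness ``d_shell``) carved out of
a pre-solvated, equilibrated snapshot, the protein heavy atoms and any
counter-ions are position-restrained, and the shell waters are left free so
they can evaporate as the temperature ramps up. Counter-ions neutralising the
net charge are placed on deterministic spherical directions at distance
``d_ion`` from the protein surface. This module builds that geometry and
emits the coordinate file, restraint listing and a key-value parameter
template per replicate for an external MD engine; it never runs dynamics
itself.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .parch_scoring import AnnealingSchedule
from .structures_io import (Atom, Residue, ResidueKey, Structure,
                            write_structure)

logger = logging.getLogger("parch")

__all__ = [
    "ShellParams",
    "ShellSystem",
    "ShellError",
    "carve_water_shell",
    "place_counterions",
    "emit_annealing_inputs",
]


class ShellError(ValueError):
    """Raised when shell carving or ion placement cannot satisfy geometry."""


@dataclass(frozen=True)
class ShellParams:
    """Geometry and restraint constants of the annealing system.

    d_shell: water-shell thickness (nm) — a water is kept iff its oxygen lies
    within this distance of some protein heavy atom, boundary inclusive.
    restraint_k: position-restraint force constant (kJ mol⁻¹ nm⁻²) applied to
    protein heavy atoms and counter-ions.
    d_ion: minimum counter-ion-to-protein-heavy-atom distance (nm).
    d_b: ion-box boundary margin (nm).
    min_tol: steepest-descent energy-minimisation force tolerance (kJ mol⁻¹ nm⁻¹).
    """

    d_shell: float = 0.415
    restraint_k: float = 1.0e4
    d_ion: float = 3.0
    d_b: float = 3.0
    min_tol: float = 1.0e3

    def __post_init__(self) -> None:
        for name in ("d_shell", "restraint_k", "d_ion", "d_b", "min_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ShellSystem:
    """A carved annealing system: protein + shell waters (+ counter-ions)."""

    structure: Structure
    shell_waters: list[ResidueKey]
    counterions: list[tuple[str, np.ndarray]] = field(default_factory=list)
    restrained_serials: list[int] = field(default_factory=list)
    params: ShellParams = field(default_factory=ShellParams)
    net_charge: int = 0

    @property
    def protein(self) -> Structure:
        return Structure(residues=[copy.deepcopy(r)
                                   for r in self.structure.protein_residues])


def carve_water_shell(solvated: Structure,
                      params: ShellParams = ShellParams(),
                      net_charge: int | None = None) -> ShellSystem:
    """Retain only the waters whose oxygen lies within ``d_shell`` of the protein.

    The protein is kept unchanged; bulk waters (and any free bulk ions, which
    the protocol replaces with its own restrained counter-ions) are removed.

    Raises
    ------
    ShellError
        If no water oxygen lies within ``d_shell`` of a protein heavy atom.
    """
    waters = solvated.water_residues
    if not waters:
        raise ShellError("solvated structure contains no waters")
    heavy_coords, heavy_serials = solvated.protein_heavy_atoms()
    tree = cKDTree(heavy_coords)

    kept: list[Residue] = []
    for res in waters:
        probe = res.probe_oxygen()
        if probe is None:
            continue
        d, _ = tree.query(probe.coordinates)
        if d <= params.d_shell + 1e-12:  # boundary inclusive
            kept.append(copy.deepcopy(res))
    if not kept:
        raise ShellError(f"no waters within d_shell={params.d_shell} nm of the protein")

    residues = [copy.deepcopy(r) for r in solvated.protein_residues] + kept
    structure = Structure(residues=_renumber_serials(residues))
    charge = solvated.net_charge if net_charge is None else net_charge
    if charge is None:
        from .structures_io import formal_net_charge
        charge = formal_net_charge(solvated)
    restrained = [a.serial for r in structure.protein_residues
                  for a in r.atoms if a.is_heavy]
    logger.info("carved shell: %d/%d waters kept at d_shell=%.3f nm",
                len(kept), len(waters), params.d_shell)
    return ShellSystem(structure=structure, shell_waters=[r.key for r in kept],
                       restrained_serials=restrained, params=params,
                       net_charge=int(charge))


def _renumber_serials(residues: list[Residue]) -> list[Residue]:
    serial = 0
    for res in residues:
        for atom in res.atoms:
            serial += 1
            atom.serial = serial
    return residues


def _fibonacci_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """n near-uniform unit vectors on the sphere, with a seeded random rotation."""
    i = np.arange(n, dtype=float)
    golden = (1 + 5 ** 0.5) / 2
    z = 1 - (2 * i + 1) / n
    theta = 2 * np.pi * i / golden
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    dirs = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    # seeded rotation so distinct seeds give distinct (still deterministic) layouts
    q = rng.normal(size=(3, 3))
    rot, _ = np.linalg.qr(q)
    if np.linalg.det(rot) < 0:
        rot[:, 0] *= -1
    return dirs @ rot.T


def box_vectors(structure: Structure, params: ShellParams) -> np.ndarray:
    """Cubic box edge lengths: protein extent plus margin on each side."""
    coords, _ = structure.protein_heavy_atoms()
    extent = coords.max(axis=0) - coords.min(axis=0)
    margin = max(params.d_b, params.d_ion + 0.5)
    edge = float(extent.max() + 2 * margin)
    return np.array([edge, edge, edge])


def place_counterions(system: ShellSystem, net_charge: int | None = None,
                      params: ShellParams | None = None,
                      seed: int = 1) -> ShellSystem:
    """Add monovalent counter-ions neutralising the system's net charge.

    |net_charge| ions of the opposing sign (NA for a negative system, CL for a
    positive one) are placed on spherical-Fibonacci directions from the protein
    centroid, each at distance ≥ ``d_ion`` from every protein heavy atom and
    inside the box margin. Ions are appended to the restrained selection.
    """
    params = params or system.params
    charge = system.net_charge if net_charge is None else int(net_charge)
    if charge == 0:
        return system

    n_ions = abs(charge)
    species = "NA" if charge < 0 else "CL"
    heavy_coords, _ = system.structure.protein_heavy_atoms()
    centroid = heavy_coords.mean(axis=0)
    tree = cKDTree(heavy_coords)
    rng = np.random.default_rng(seed)
    dirs = _fibonacci_directions(max(n_ions, 2), rng)[:n_ions]

    box = box_vectors(system.structure, params)
    center = 0.5 * (heavy_coords.max(axis=0) + heavy_coords.min(axis=0))
    lo, hi = center - box / 2, center + box / 2

    residues = [copy.deepcopy(r) for r in system.structure.residues]
    max_seq = max(r.seq_number for r in residues)
    serial = sum(len(r.atoms) for r in residues)
    ions: list[tuple[str, np.ndarray]] = list(system.counterions)
    ion_serials: list[int] = []
    for k, direction in enumerate(dirs):
        # walk outward until the d_ion clearance is met
        r = params.d_ion
        pos = centroid + direction * r
        while tree.query(pos)[0] < params.d_ion - 1e-12:
            r += 0.05
            pos = centroid + direction * r
        if np.any(pos < lo) or np.any(pos > hi):
            raise ShellError(
                f"cannot place ion {k + 1}/{n_ions} at >= d_ion={params.d_ion} nm "
                f"inside the box (margin d_b={params.d_b} nm)")
        serial += 1
        ion_serials.append(serial)
        residues.append(Residue(
            chain_id="I", seq_number=max_seq + k + 1, name=species,
            atoms=[Atom(serial=serial, name=species, element=species.capitalize(),
                        coordinates=pos)],
            is_ion=True))
        ions.append((species, pos.copy()))

    structure = Structure(residues=_renumber_serials(residues))
    restrained = [a.serial for r in structure.protein_residues
                  for a in r.atoms if a.is_heavy]
    restrained += [r.atoms[0].serial for r in structure.ion_residues]
    logger.info("placed %d %s counter-ions at >= d_ion=%.1f nm", n_ions, species,
                params.d_ion)
    return ShellSystem(structure=structure, shell_waters=list(system.shell_waters),
                       counterions=ions, restrained_serials=restrained,
                       params=params, net_charge=charge + n_ions * (1 if species == "NA" else -1))


def emit_annealing_inputs(system: ShellSystem,
                          schedule: AnnealingSchedule = AnnealingSchedule(),
                          outdir: str | Path = ".",
                          n_replicates: int = 5,
                          base_seed: int = 1,
                          coord_format: str = "gro") -> dict:
    """Write coordinates, restraint listing and per-replicate ramp templates.

    Returns a manifest (also written as ``manifest.json``) listing every file.
    The parameter template is a documented key-value file encoding the NVT
    annealing ramp, minimisation tolerance and replicate seed, for the user to
    translate into their MD engine's input format.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create output directory {outdir}: {exc}") from exc

    params = system.params
    files: dict[str, str] = {}

    coord_path = outdir / f"system.{coord_format}"
    write_structure(system.structure, coord_path)
    files["coordinates"] = coord_path.name

    restr_path = outdir / "restraints.txt"
    with open(restr_path, "w") as fh:
        fh.write("# position-restrained atom serials "
                 f"(k = {params.restraint_k:g} kJ mol^-1 nm^-2)\n")
        fh.write("# protein heavy atoms and counter-ions; shell waters are free\n")
        for serial in system.restrained_serials:
            fh.write(f"{serial}\n")
    files["restraints"] = restr_path.name

    duration = schedule.duration
    template_names = []
    for rep in range(1, n_replicates + 1):
        tpl = outdir / f"annealing_rep{rep}.mdp"
        with open(tpl, "w") as fh:
            fh.write(
                "; NVT annealing ramp template (key-value; adapt to your engine)\n"
                "integrator               = md\n"
                "ensemble                 = NVT\n"
                f"dt                       = 0.002\n"
                f"nsteps                   = {int(duration / 0.002)}\n"
                "annealing                = single\n"
                "annealing-npoints        = 2\n"
                f"annealing-time           = 0 {duration:g}\n"
                f"annealing-temp           = {schedule.T_start:g} {schedule.T_end:g}\n"
                f"heating-rate-K-per-ps    = {schedule.rate:g}\n"
                f"emtol                    = {params.min_tol:g}\n"
                f"restraint-fc             = {params.restraint_k:g}\n"
                f"d-shell-nm               = {params.d_shell:g}\n"
                f"gen-vel                  = yes\n"
                f"gen-seed                 = {base_seed + rep - 1}\n")
        template_names.append(tpl.name)
    files["templates"] = template_names  # type: ignore[assignment]

    manifest = {
        "coordinates": files["coordinates"],
        "restraints": files["restraints"],
        "templates": template_names,
        "n_replicates": n_replicates,
        "base_seed": base_seed,
        "ramp": {"T_start": schedule.T_start, "T_end": schedule.T_end,
                 "rate_K_per_ps": schedule.rate, "duration_ps": duration},
        "params": {"d_shell": params.d_shell, "restraint_k": params.restraint_k,
                   "d_ion": params.d_ion, "d_b": params.d_b,
                   "min_tol": params.min_tol},
        "n_shell_waters": len(system.shell_waters),
        "n_counterions": len(system.counterions),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    files["manifest"] = "manifest.json"
    logger.info("annealing inputs written to %s (%d replicates)", outdir,
                n_replicates)
    return manifest
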