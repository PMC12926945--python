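"""Structure and trajectory I/O with modified-residue awareness.

This module owns the in-memory containers the rest of the pipeline runs on:
:class:`Structure` (residues → atoms, with solvent/ion flags), :class:`Trajectory`
(per-frame coordinate arrays congruent with a structure), :class:`PTMSite`
(a recognised post-translationally modified residue) and :class:`ResidueMapping`
(residue-level pairing between an unmodified and a modified variant of the same
protein, obtained by global sequence alignment).

File parsing and writing are delegated to MDAnalysis (PDB/GRO coordinates,
XTC/DCD/multi-model-PDB trajectories); all coordinates are stored internally in
nanometres, residue numbering follows the source file verbatim, and every
internal residue key is the pair ``(chain_id, seq_number)``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

logger = logging.getLogger("parch")

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Trajectory",
    "PTMSite",
    "ResidueMapping",
    "PTM_RECOGNITION_TABLE",
    "parse_structure",
    "parse_trajectory",
    "write_structure",
    "write_trajectory",
    "identify_ptm_sites",
    "map_residues",
    "formal_net_charge",
    "StructureError",
    "TrajectoryError",
    "MappingError",
]


class StructureError(ValueError):
    """Raised for malformed or empty structures."""


class TrajectoryError(ValueError):
    """Raised for trajectories incongruent with their structure."""


class MappingError(ValueError):
    """Raised when two variants cannot be aligned confidently."""


# ---------------------------------------------------------------------------
# Residue chemistry tables
# ---------------------------------------------------------------------------

#: Canonical three-letter → one-letter codes.
_CANONICAL_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common histidine protonation-state aliases
    "HSD": "H", "HSE": "H", "HSP": "H", "HID": "H", "HIE": "H", "HIP": "H",
}

#: Recognition table for modified residues: code → (mod_type, parent one-letter).
#: ph = phosphorylation, ac = N-lysine acetylation, me = monomethylation.
#: Config-extensible; these are the defaults for standard wwPDB chemical
#: component codes.
PTM_RECOGNITION_TABLE: dict[str, tuple[str, str]] = {
    "SEP": ("ph", "S"),   # phosphoserine
    "TPO": ("ph", "T"),   # phosphothreonine
    "PTR": ("ph", "Y"),   # phosphotyrosine
    "ALY": ("ac", "K"),   # N6-acetyllysine
    "MLZ": ("me", "K"),   # N6-methyllysine
    "MLY": ("me", "K"),   # methylated lysine (dimethyl code, accepted as me)
    "NMM": ("me", "R"),   # omega-N-methylarginine
    "AGM": ("me", "R"),   # 5-methylarginine
}

_WATER_NAMES = {"HOH", "SOL", "WAT", "TIP", "TIP3", "TIP3P", "TIP4", "TIP4P",
                "SPC", "SPCE", "T3P", "W"}

_ION_NAMES = {"NA", "CL", "K", "MG", "CA", "ZN", "SOD", "CLA", "POT", "CAL",
              "NA+", "CL-", "K+", "MG2", "LI", "RB", "CS", "BR", "F", "IOD"}

_ION_CHARGES = {
    "NA": 1, "SOD": 1, "NA+": 1, "K": 1, "POT": 1, "K+": 1, "LI": 1,
    "RB": 1, "CS": 1,
    "CL": -1, "CLA": -1, "CL-": -1, "BR": -1, "F": -1, "IOD": -1,
    "MG": 2, "MG2": 2, "CA": 2, "CAL": 2, "ZN": 2,
}

#: Formal side-chain charges at neutral pH for net-charge bookkeeping.
_RESIDUE_CHARGES = {
    "ASP": -1, "GLU": -1, "LYS": 1, "ARG": 1, "HSP": 1, "HIP": 1,
    # phosphorylated residues carry a -2 phosphate; lysine acetylation
    # neutralises the +1; monomethylation preserves charge.
    "SEP": -3, "TPO": -3, "PTR": -2,
    "ALY": 0, "MLZ": 1, "MLY": 1, "NMM": 1, "AGM": 1,
}

_TWO_LETTER_ELEMENTS = {"NA", "CL", "MG", "CA", "ZN", "FE", "MN", "BR", "LI",
                        "RB", "CS", "SE"}


def _guess_element(atom_name: str, resname: str = "") -> str:
    """Element from an atom name, PDB conventions (``1HG1`` → H, ``OW`` → O)."""
    name = atom_name.strip().upper()
    if resname.strip().upper() in _ION_NAMES and name in _TWO_LETTER_ELEMENTS:
        return name.capitalize()
    stripped = name.lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[:2] in _TWO_LETTER_ELEMENTS and resname.strip().upper() in _ION_NAMES:
        return stripped[:2].capitalize()
    return stripped[0]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

ResidueKey = tuple[str, int]


@dataclass
class Atom:
    """A single atom; coordinates in nm."""

    serial: int
    name: str
    element: str
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (3,) or not np.all(np.isfinite(self.coordinates)):
            raise StructureError(f"atom {self.serial}: coordinates must be a finite 3-vector")
        if self.serial < 1:
            raise StructureError(f"atom serial must be >= 1, got {self.serial}")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Residue:
    """A residue (amino acid, water, or ion) with its ordered atoms."""

    chain_id: str
    seq_number: int
    name: str
    atoms: list[Atom]
    is_solvent: bool = False
    is_ion: bool = False

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(f"residue {self.name} {self.seq_number}: needs >= 1 atom")

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_number)

    @property
    def is_protein(self) -> bool:
        return not (self.is_solvent or self.is_ion)

    @property
    def parent_code(self) -> str | None:
        """One-letter code of the canonical parent amino acid (None if unknown)."""
        name = self.name.upper()
        if name in _CANONICAL_3TO1:
            return _CANONICAL_3TO1[name]
        if name in PTM_RECOGNITION_TABLE:
            return PTM_RECOGNITION_TABLE[name][1]
        return None

    def heavy_coordinates(self) -> np.ndarray:
        return np.array([a.coordinates for a in self.atoms if a.is_heavy], dtype=float)

    def probe_oxygen(self) -> Atom | None:
        """First oxygen atom (water contact probe); None if the residue has no O."""
        for atom in self.atoms:
            if atom.element.upper() == "O":
                return atom
        return None


@dataclass
class Structure:
    """An ordered collection of residues; the topology every frame refers to."""

    residues: list[Residue]
    net_charge: int | None = None

    def __post_init__(self) -> None:
        seen: set[ResidueKey] = set()
        for res in self.residues:
            if res.key in seen:
                raise StructureError(f"duplicate residue key {res.key}")
            seen.add(res.key)
        self._index: dict[ResidueKey, Residue] = {r.key: r for r in self.residues}

    # -- bookkeeping -------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def coordinates(self) -> np.ndarray:
        """All atom coordinates, (n_atoms, 3), nm, in residue/atom order."""
        return np.concatenate([
            np.array([a.coordinates for a in r.atoms]) for r in self.residues
        ])

    def set_coordinates(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise StructureError(
                f"coordinate array shape {coords.shape} != ({self.n_atoms}, 3)")
        i = 0
        for res in self.residues:
            for atom in res.atoms:
                atom.coordinates = coords[i]
                i += 1

    def atom_slices(self) -> dict[ResidueKey, slice]:
        """Residue key → slice into the flat atom/coordinate arrays."""
        out: dict[ResidueKey, slice] = {}
        i = 0
        for res in self.residues:
            out[res.key] = slice(i, i + len(res.atoms))
            i += len(res.atoms)
        return out

    def residue(self, key: ResidueKey) -> Residue:
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(f"no residue with key {key}") from None

    def __contains__(self, key: ResidueKey) -> bool:
        return key in self._index

    @property
    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_protein]

    @property
    def water_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_solvent]

    @property
    def ion_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.is_ion]

    def protein_heavy_atoms(self) -> tuple[np.ndarray, list[int]]:
        """(coords, serials) of every heavy atom in every protein residue."""
        coords, serials = [], []
        for res in self.protein_residues:
            for atom in res.atoms:
                if atom.is_heavy:
                    coords.append(atom.coordinates)
                    serials.append(atom.serial)
        if not coords:
            raise StructureError("structure has no protein heavy atoms")
        return np.array(coords), serials


@dataclass
class Trajectory:
    """Frames congruent with one Structure; times in ps, coordinates in nm."""

    frame_times: np.ndarray
    frames: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] != len(self.frame_times):
            raise TrajectoryError("frames must be (n_frames, n_atoms, 3) matching frame_times")
        if len(self.frame_times) and self.frame_times[0] < 0:
            raise TrajectoryError("frame_times[0] must be >= 0")
        if np.any(np.diff(self.frame_times) <= 0):
            raise TrajectoryError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass(frozen=True)
class PTMSite:
    """A recognised modified residue: phosphorylation, acetylation or methylation."""

    chain_id: str
    seq_number: int
    mod_type: str          # "ph" | "ac" | "me"
    modified_name: str

    def __post_init__(self) -> None:
        expected = PTM_RECOGNITION_TABLE.get(self.modified_name.upper())
        if expected is None or expected[0] != self.mod_type:
            raise StructureError(
                f"mod_type {self.mod_type!r} inconsistent with residue "
                f"{self.modified_name!r} per the recognition table")

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_number)


@dataclass
class ResidueMapping:
    """One-to-one residue pairing between an unmodified and a modified variant."""

    pairs: list[tuple[ResidueKey, ResidueKey]]
    unmatched_unmod: list[ResidueKey] = field(default_factory=list)
    unmatched_mod: list[ResidueKey] = field(default_factory=list)

    def __post_init__(self) -> None:
        lefts = [p[0] for p in self.pairs]
        rights = [p[1] for p in self.pairs]
        if len(set(lefts)) != len(lefts) or len(set(rights)) != len(rights):
            raise MappingError("mapping is not one-to-one")
        self.u2m: dict[ResidueKey, ResidueKey] = dict(self.pairs)
        self.m2u: dict[ResidueKey, ResidueKey] = {m: u for u, m in self.pairs}


# ---------------------------------------------------------------------------
# Parsing / writing (MDAnalysis backend)
# ---------------------------------------------------------------------------

def _mda():
    import MDAnalysis
    return MDAnalysis


def parse_structure(path: str | Path, fmt: str | None = None) -> Structure:
    """Read a PDB or GRO file into a :class:`Structure`.

    All ATOM/HETATM records are represented; waters are flagged ``is_solvent``,
    monoatomic ions ``is_ion``; coordinates are converted to nm.

    Parameters
    ----------
    path:
        Coordinate file. Format is inferred from the extension unless ``fmt``
        (``"pdb"`` or ``"gro"``) is given.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"structure file not found: {path}")
    mda = _mda()
    kwargs = {"format": fmt.upper()} if fmt else {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path), **kwargs)
        except Exception as exc:  # noqa: BLE001 - surface as I/O error
            raise IOError(f"could not read structure {path}: {exc}") from exc

    atoms = u.atoms
    try:
        elements = [str(e) for e in atoms.elements]
    except Exception:  # noqa: BLE001 - topology without elements (e.g. GRO)
        elements = [""] * len(atoms)

    residues: list[Residue] = []
    serial = 0
    for res in u.residues:
        resname = str(res.resname).strip()
        chain = ""
        first = res.atoms[0]
        for attr in ("chainID", "segid"):
            val = str(getattr(first, attr, "")).strip()
            if val and val != "SYSTEM":
                chain = val
                break
        chain = chain or "A"
        ratoms: list[Atom] = []
        for a in res.atoms:
            serial += 1
            elem = elements[a.ix].strip() or _guess_element(str(a.name), resname)
            ratoms.append(Atom(
                serial=serial,
                name=str(a.name).strip(),
                element=elem.capitalize(),
                coordinates=np.asarray(a.position, dtype=float) / 10.0,  # A -> nm
            ))
        upper = resname.upper()
        is_water = upper in _WATER_NAMES
        is_ion = (not is_water) and upper in _ION_NAMES and len(ratoms) == 1
        residues.append(Residue(
            chain_id=chain, seq_number=int(res.resid), name=resname,
            atoms=ratoms, is_solvent=is_water, is_ion=is_ion,
        ))

    # duplicate (chain, resid) across e.g. protein chain and waters sharing ids:
    # disambiguate waters/ions into their own chain namespaces if they collide.
    residues = _deduplicate_keys(residues)
    structure = Structure(residues=residues)
    if not structure.protein_residues:
        raise StructureError(f"{path}: no protein residues found")
    return structure


def _deduplicate_keys(residues: list[Residue]) -> list[Residue]:
    seen: set[ResidueKey] = set()
    for res in residues:
        if res.key in seen:
            suffix = "w" if res.is_solvent else ("i" if res.is_ion else "x")
            new_chain = res.chain_id + suffix
            while (new_chain, res.seq_number) in seen:
                new_chain += suffix
            res.chain_id = new_chain
        seen.add(res.key)
    return residues


def formal_net_charge(structure: Structure) -> int:
    """Net formal charge from residue/ion bookkeeping at neutral pH.

    Side chains: Asp/Glu −1, Lys/Arg +1; phospho-residues include the −2
    phosphate; acetyl-lysine is neutral; ions per species. Termini are not
    counted (they cancel for a single chain).
    """
    charge = 0
    for res in structure.residues:
        name = res.name.upper()
        if res.is_ion:
            charge += _ION_CHARGES.get(name, 0)
        elif res.is_protein:
            charge += _RESIDUE_CHARGES.get(name, 0)
    return charge


def _build_universe(structure: Structure):
    """Assemble an MDAnalysis Universe mirroring the structure (for writing)."""
    mda = _mda()
    n_atoms = structure.n_atoms
    n_res = len(structure.residues)
    atom_resindex = np.concatenate([
        np.full(len(r.atoms), i) for i, r in enumerate(structure.residues)
    ])
    u = mda.Universe.empty(
        n_atoms, n_residues=n_res, n_segments=1,
        atom_resindex=atom_resindex,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.name for a in structure.atoms])
    u.add_TopologyAttr("elements", [a.element for a in structure.atoms])
    u.add_TopologyAttr("resnames", [r.name for r in structure.residues])
    u.add_TopologyAttr("resids", [r.seq_number for r in structure.residues])
    u.add_TopologyAttr("chainIDs", np.concatenate([
        np.full(len(r.atoms), r.chain_id[:1] or "A", dtype=object)
        for r in structure.residues
    ]))
    u.add_TopologyAttr("segids", ["SYSTEM"])
    u.atoms.positions = structure.coordinates() * 10.0  # nm -> A
    return u


def write_structure(structure: Structure, path: str | Path) -> Path:
    """Write a Structure as PDB or GRO (by extension), coordinates nm → file units."""
    path = Path(path)
    u = _build_universe(structure)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))
    return path


def parse_trajectory(path: str | Path, structure: Structure,
                     dt: float | None = None) -> Trajectory:
    """Read an XTC/DCD/multi-model-PDB trajectory congruent with ``structure``.

    Parameters
    ----------
    dt:
        Frame spacing in ps, used when the format carries no time information
        (multi-model PDB) or to override file times.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"trajectory file not found: {path}")
    mda = _mda()
    n_atoms = structure.n_atoms
    u = mda.Universe.empty(n_atoms, trajectory=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u.load_new(str(path))
        except Exception as exc:  # noqa: BLE001
            raise TrajectoryError(
                f"could not read trajectory {path} with {n_atoms} atoms: {exc}"
            ) from exc

    frames, times = [], []
    box = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            if ts.positions.shape[0] != n_atoms:
                raise TrajectoryError(
                    f"frame has {ts.positions.shape[0]} atoms, structure has {n_atoms}")
            frames.append(ts.positions.copy() / 10.0)
            times.append(float(ts.time))
            if ts.dimensions is not None and ts.dimensions[:3].any():
                box = np.asarray(ts.dimensions[:3], dtype=float) / 10.0
    times_arr = np.asarray(times)
    diffs = np.diff(times_arr)
    if dt is not None or (len(times_arr) > 1 and np.all(diffs == 0)):
        # format carries no time information (multi-model PDB) or caller override
        step = dt if dt is not None else 1.0
        times_arr = np.arange(len(frames)) * step
    elif np.any(diffs <= 0):
        raise TrajectoryError(f"{path}: frame times are not strictly increasing")
    return Trajectory(frame_times=times_arr, frames=np.asarray(frames), box=box)


def write_trajectory(traj: Trajectory, structure: Structure,
                     path: str | Path) -> Path:
    """Write a trajectory (XTC, DCD or multi-model PDB, by extension)."""
    path = Path(path)
    if traj.n_atoms != structure.n_atoms:
        raise TrajectoryError("trajectory not congruent with structure")
    mda = _mda()
    u = _build_universe(structure)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=structure.n_atoms) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.frames[i] * 10.0
                u.trajectory.ts.time = float(traj.frame_times[i])
                u.trajectory.ts.frame = i
                if traj.box is not None:
                    u.trajectory.ts.dimensions = [*(traj.box * 10.0), 90, 90, 90]
                w.write(u.atoms)
    return path


# ---------------------------------------------------------------------------
# PTM recognition and residue mapping
# ---------------------------------------------------------------------------

def identify_ptm_sites(structure: Structure,
                       table: Mapping[str, tuple[str, str]] | None = None,
                       ) -> list[PTMSite]:
    """Scan a structure for modified residues per the recognition table.

    Unknown nonstandard residue names are skipped with a logged warning.
    """
    table = dict(PTM_RECOGNITION_TABLE if table is None else table)
    sites: list[PTMSite] = []
    for res in structure.protein_residues:
        name = res.name.upper()
        if name in table:
            sites.append(PTMSite(
                chain_id=res.chain_id, seq_number=res.seq_number,
                mod_type=table[name][0], modified_name=name))
        elif name not in _CANONICAL_3TO1:
            logger.warning("unknown nonstandard residue %s %s:%d skipped",
                           res.name, res.chain_id, res.seq_number)
    return sites


def _chain_sequences(structure: Structure) -> dict[str, list[Residue]]:
    chains: dict[str, list[Residue]] = {}
    for res in structure.protein_residues:
        chains.setdefault(res.chain_id, []).append(res)
    return chains


def map_residues(unmod: Structure, mod: Structure,
                 min_identity: float = 0.9) -> ResidueMapping:
    """Pair residues of two protein variants by global sequence alignment.

    Parent one-letter codes are aligned per chain (match=1, mismatch=0,
    gap=−1), so a modified residue pairs with its canonical parent at the same
    aligned position. Chains sharing an id are aligned together; leftovers are
    paired in file order.

    Raises
    ------
    MappingError
        If alignment identity over aligned columns falls below ``min_identity``.
    """
    from Bio import Align

    uc, mc = _chain_sequences(unmod), _chain_sequences(mod)
    if not uc or not mc:
        raise MappingError("both structures need at least one protein residue")

    shared = [c for c in uc if c in mc]
    extra_u = [c for c in uc if c not in mc]
    extra_m = [c for c in mc if c not in uc]
    chain_pairs = [(c, c) for c in shared] + list(zip(extra_u, extra_m))
    unmatched_u = [r.key for c in extra_u[len(extra_m):] for r in uc[c]]
    unmatched_m = [r.key for c in extra_m[len(extra_u):] for r in mc[c]]

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1

    pairs: list[tuple[ResidueKey, ResidueKey]] = []
    for cu, cm in chain_pairs:
        res_u, res_m = uc[cu], mc[cm]
        seq_u = "".join(r.parent_code or "X" for r in res_u)
        seq_m = "".join(r.parent_code or "X" for r in res_m)
        aln = aligner.align(seq_u, seq_m)[0]
        matched_u: set[int] = set()
        matched_m: set[int] = set()
        n_match = n_cols = 0
        for (us, ue), (ms, me) in zip(*aln.aligned):
            for i, j in zip(range(us, ue), range(ms, me)):
                pairs.append((res_u[i].key, res_m[j].key))
                matched_u.add(i)
                matched_m.add(j)
                n_cols += 1
                if seq_u[i] == seq_m[j]:
                    n_match += 1
        identity = n_match / n_cols if n_cols else 0.0
        if identity < min_identity:
            raise MappingError(
                f"chains {cu}/{cm}: alignment identity {identity:.2f} below "
                f"floor {min_identity:.2f}")
        unmatched_u += [res_u[i].key for i in range(len(res_u)) if i not in matched_u]
        unmatched_m += [res_m[j].key for j in range(len(res_m)) if j not in matched_m]

    return ResidueMapping(pairs=pairs, unmatched_unmod=unmatched_u,
                          unmatched_mod=unmatched_m)
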