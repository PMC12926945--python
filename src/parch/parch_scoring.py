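"""Per-residue hydropathy scoring from water-retention during annealing.

The score ("PARCH value", PV) runs from 0 (hydrophobic: the residue sheds its
contact waters early in the heating ramp) to 10 (hydrophilic: it retains them
to the end). The pipeline is: map frame time to temperature along a linear
ramp → count distinct water contacts per residue per frame (water-oxygen to
residue-heavy-atom distance ≤ d_water, boundary inclusive) → reduce each
evaporation profile to a PV — by default the retention ratio between the final
and initial windows of the ramp, scaled to [0, 10] — → aggregate replicate
runs into per-residue mean ± sd.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structures_io import ResidueKey, Structure, Trajectory

__all__ = [
    "AnnealingSchedule",
    "ContactParams",
    "EvaporationProfile",
    "PVResult",
    "ParchProfile",
    "temperature_at",
    "count_water_contacts",
    "build_profiles",
    "parch_from_profile",
    "retention_ratio_scorer",
    "escape_temperature_scorer",
    "aggregate_replicates",
]


@dataclass(frozen=True)
class AnnealingSchedule:
    """Linear NVT heating ramp: 300 → 800 K at 1 K per 10 ps by default."""

    T_start: float = 300.0   # K
    T_end: float = 800.0     # K
    rate: float = 0.1        # K/ps
    frame_interval: float = 10.0  # ps between analysis frames

    def __post_init__(self) -> None:
        if self.T_end <= self.T_start:
            raise ValueError("T_end must exceed T_start")
        if self.rate <= 0:
            raise ValueError("heating rate must be positive")

    @property
    def duration(self) -> float:
        """Ramp duration in ps (5000 ps for the default 500 K at 0.1 K/ps)."""
        return (self.T_end - self.T_start) / self.rate


@dataclass(frozen=True)
class ContactParams:
    """Water-contact definition: probe vs target atoms and the cutoff."""

    d_water: float = 0.315       # nm, contact cutoff, boundary inclusive
    water_probe: str = "oxygen"  # contact locus on the water molecule
    residue_target: str = "heavy"  # atoms of the residue considered

    def __post_init__(self) -> None:
        if self.d_water <= 0:
            raise ValueError("d_water must be positive")
        if self.water_probe != "oxygen" or self.residue_target != "heavy":
            raise ValueError("only oxygen-probe / heavy-target selections are defined")


@dataclass
class EvaporationProfile:
    """Water-contact count of one residue along the heating ramp."""

    residue_key: ResidueKey
    counts: np.ndarray        # per-frame distinct-water contact counts
    temperatures: np.ndarray  # per-frame K, non-decreasing

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if self.counts.shape != self.temperatures.shape:
            raise ValueError("counts and temperatures must be congruent")
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be non-negative")
        if np.any(np.diff(self.temperatures) < 0):
            raise ValueError("temperatures must be non-decreasing")


@dataclass(frozen=True)
class PVResult:
    """A single-replicate PARCH value with the buried-residue flag."""

    pv: float
    buried: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.pv <= 10.0:
            raise ValueError(f"PV must lie in [0, 10], got {self.pv}")


def temperature_at(schedule: AnnealingSchedule, t: float) -> float:
    """Temperature (K) at ramp time ``t`` ps; clamped at T_end past the ramp."""
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    return min(schedule.T_start + schedule.rate * t, schedule.T_end)


# ---------------------------------------------------------------------------
# Contact counting
# ---------------------------------------------------------------------------

def _water_probes(structure: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Flat-array indices and owning-water indices of every water probe oxygen."""
    slices = structure.atom_slices()
    idx, owner = [], []
    for w, res in enumerate(structure.water_residues):
        probe = res.probe_oxygen()
        if probe is None:
            continue
        base = slices[res.key].start
        idx.append(base + res.atoms.index(probe))
        owner.append(w)
    return np.asarray(idx, dtype=int), np.asarray(owner, dtype=int)


def _heavy_indices(structure: Structure, key: ResidueKey) -> np.ndarray:
    res = structure.residue(key)
    base = structure.atom_slices()[key].start
    return np.asarray([base + i for i, a in enumerate(res.atoms) if a.is_heavy],
                      dtype=int)


def count_water_contacts(frame: np.ndarray, structure: Structure,
                         residue_key: ResidueKey,
                         params: ContactParams = ContactParams()) -> int:
    """Distinct waters with probe oxygen within ``d_water`` of the residue.

    Each water counts at most once per residue regardless of how many of the
    residue's heavy atoms it touches. The cutoff is inclusive.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (structure.n_atoms, 3):
        raise ValueError(f"frame shape {frame.shape} incongruent with structure")
    heavy = _heavy_indices(structure, residue_key)  # raises KeyError if absent
    probe_idx, owner = _water_probes(structure)
    if len(probe_idx) == 0 or len(heavy) == 0:
        return 0
    tree = cKDTree(frame[probe_idx])
    hits = tree.query_ball_point(frame[heavy], r=params.d_water)
    touched = {owner[j] for lst in hits for j in lst}
    return len(touched)


def build_profiles(traj: Trajectory, structure: Structure,
                   schedule: AnnealingSchedule = AnnealingSchedule(),
                   params: ContactParams = ContactParams(),
                   ) -> list[EvaporationProfile]:
    """One evaporation profile per protein residue over the whole trajectory."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    if traj.n_atoms != structure.n_atoms:
        raise ValueError("trajectory incongruent with structure")
    probe_idx, owner = _water_probes(structure)
    protein = structure.protein_residues
    slices = structure.atom_slices()
    heavy_by_res = []
    for res in protein:
        base = slices[res.key].start
        heavy_by_res.append(np.asarray(
            [base + i for i, a in enumerate(res.atoms) if a.is_heavy], dtype=int))

    temps = np.array([temperature_at(schedule, t) for t in traj.frame_times])
    counts = np.zeros((len(protein), traj.n_frames), dtype=int)
    for f in range(traj.n_frames):
        frame = traj.frames[f]
        if len(probe_idx) == 0:
            continue
        tree = cKDTree(frame[probe_idx])
        for r, heavy in enumerate(heavy_by_res):
            if len(heavy) == 0:
                continue
            hits = tree.query_ball_point(frame[heavy], r=params.d_water)
            counts[r, f] = len({owner[j] for lst in hits for j in lst})

    return [EvaporationProfile(residue_key=res.key, counts=counts[r],
                               temperatures=temps)
            for r, res in enumerate(protein)]


# ---------------------------------------------------------------------------
# Scoring strategies
# ---------------------------------------------------------------------------

Scorer = Callable[[EvaporationProfile, float, float], PVResult]


def retention_ratio_scorer(profile: EvaporationProfile,
                           w_init: float = 0.05,
                           w_final: float = 0.05) -> PVResult:
    """PV = 10 · clamp(final-window mean / initial-window mean, 0, 1).

    A residue whose initial window holds no water at all (buried) gets PV 0
    with the buried flag set, since a retention ratio is undefined for it.
    """
    if not 0 < w_init <= 0.5 or not 0 < w_final <= 0.5:
        raise ValueError("window fractions must lie in (0, 0.5]")
    n = len(profile.counts)
    if n == 0:
        raise ValueError("empty profile")
    ni = max(1, round(w_init * n))
    nf = max(1, round(w_final * n))
    init_mean = float(np.mean(profile.counts[:ni]))
    final_mean = float(np.mean(profile.counts[-nf:]))
    if init_mean == 0.0:
        return PVResult(pv=0.0, buried=True)
    return PVResult(pv=10.0 * min(max(final_mean / init_mean, 0.0), 1.0))


def escape_temperature_scorer(profile: EvaporationProfile,
                              w_init: float = 0.05,
                              w_final: float = 0.05) -> PVResult:
    """Alternative scorer: PV from the half-evaporation temperature.

    PV = 10 · (T_half − T_first) / (T_last − T_first), where T_half is the
    first frame temperature at which the contact count drops to half the
    initial-window mean; residues never reaching half-loss score 10.
    Provided for robustness checks of scorer-independent conclusions.
    """
    n = len(profile.counts)
    if n == 0:
        raise ValueError("empty profile")
    ni = max(1, round(w_init * n))
    init_mean = float(np.mean(profile.counts[:ni]))
    if init_mean == 0.0:
        return PVResult(pv=0.0, buried=True)
    t0, t1 = profile.temperatures[0], profile.temperatures[-1]
    if t1 <= t0:
        return PVResult(pv=10.0)
    below = np.nonzero(profile.counts <= init_mean / 2.0)[0]
    if len(below) == 0:
        return PVResult(pv=10.0)
    t_half = profile.temperatures[below[0]]
    return PVResult(pv=10.0 * min(max((t_half - t0) / (t1 - t0), 0.0), 1.0))


def parch_from_profile(profile: EvaporationProfile,
                       w_init: float = 0.05, w_final: float = 0.05,
                       scorer: Scorer = retention_ratio_scorer) -> PVResult:
    """Reduce one evaporation profile to a PARCH value via ``scorer``."""
    return scorer(profile, w_init, w_final)


# ---------------------------------------------------------------------------
# Replicate aggregation
# ---------------------------------------------------------------------------

@dataclass
class ParchProfile:
    """Per-residue PV mean ± sample sd over replicate annealing runs."""

    pv_mean: dict[ResidueKey, float]
    pv_sd: dict[ResidueKey, float]
    n_replicates: int
    buried: dict[ResidueKey, bool] = field(default_factory=dict)
    scoring_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, pv in self.pv_mean.items():
            if not 0.0 <= pv <= 10.0:
                raise ValueError(f"PV mean out of [0, 10] at {key}: {pv}")

    def __getitem__(self, key: ResidueKey) -> float:
        return self.pv_mean[key]

    def __contains__(self, key: ResidueKey) -> bool:
        return key in self.pv_mean

    def to_frame(self, structure: Structure | None = None) -> pd.DataFrame:
        rows = []
        for key, mean in self.pv_mean.items():
            resname = ""
            if structure is not None and key in structure:
                resname = structure.residue(key).name
            rows.append({
                "chain": key[0], "resnum": key[1], "resname": resname,
                "PV_mean": mean, "PV_sd": self.pv_sd[key],
                "n_rep": self.n_replicates,
                "buried_flag": int(self.buried.get(key, False)),
            })
        return pd.DataFrame(rows)

    def write_tsv(self, path, structure: Structure | None = None) -> None:
        self.to_frame(structure).to_csv(path, sep="\t", index=False,
                                        float_format="%.6g")

    @classmethod
    def read_tsv(cls, path) -> "ParchProfile":
        df = pd.read_csv(path, sep="\t", dtype={"chain": str})
        keys = [(str(c), int(n)) for c, n in zip(df["chain"], df["resnum"])]
        return cls(
            pv_mean=dict(zip(keys, df["PV_mean"].astype(float))),
            pv_sd=dict(zip(keys, df["PV_sd"].astype(float))),
            n_replicates=int(df["n_rep"].iloc[0]) if len(df) else 1,
            buried={k: bool(b) for k, b in zip(keys, df["buried_flag"])},
        )


def aggregate_replicates(
        pv_by_replicate: Sequence[Mapping[ResidueKey, PVResult]],
        scoring_params: dict | None = None) -> ParchProfile:
    """Mean and sample sd of per-residue PVs across replicate runs.

    All replicates must cover exactly the same residue keys. With a single
    replicate, sd is 0 by convention.
    """
    if not pv_by_replicate:
        raise ValueError("need at least one replicate")
    keys = list(pv_by_replicate[0].keys())
    keyset = set(keys)
    for i, rep in enumerate(pv_by_replicate[1:], start=2):
        if set(rep.keys()) != keyset:
            raise ValueError(f"replicate {i} covers different residue keys")
    n = len(pv_by_replicate)
    mean, sd, buried = {}, {}, {}
    for key in keys:
        vals = np.array([rep[key].pv for rep in pv_by_replicate])
        mean[key] = float(vals.mean())
        sd[key] = float(vals.std(ddof=1)) if n > 1 else 0.0
        buried[key] = any(rep[key].buried for rep in pv_by_replicate)
    return ParchProfile(pv_mean=mean, pv_sd=sd, n_replicates=n, buried=buried,
                        scoring_params=dict(scoring_params or {}))
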