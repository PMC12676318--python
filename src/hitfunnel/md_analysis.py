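"""Trajectory stability metrics: superposed RMSD time series, per-residue
RMSF, geometric hydrogen-bond counts, and interaction-energy summaries.

All operations work on the in-memory :class:`~hitfunnel.io_model.Trajectory`
(plain numpy frames).  The hydrogen-bond criterion is distance-only by
default — donor–acceptor separation ≤ 3.5 Å — with an optional
donor–H···acceptor angle cutoff (150° when enabled) for stricter geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_model import Trajectory
from .pose_compare import kabsch_superpose

__all__ = [
    "HBondCriteria",
    "EnergySeries",
    "BACKBONE_ATOMS",
    "traj_rmsd",
    "traj_rmsf",
    "hbond_counts",
    "energy_summary",
    "energy_ratio",
    "read_energy_series",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class HBondCriteria:
    max_donor_acceptor_distance: float = 3.5  # Å
    angle_cutoff: Optional[float] = None  # degrees D-H...A; None = distance-only

    def __post_init__(self):
        if not self.max_donor_acceptor_distance > 0:
            raise ValueError("distance cutoff must be positive")


@dataclass
class EnergySeries:
    """Per-frame short-range Coulomb and Lennard-Jones terms (kJ/mol)."""

    coul_sr: np.ndarray
    lj_sr: np.ndarray
    times: np.ndarray  # ns

    def __post_init__(self):
        self.coul_sr = np.asarray(self.coul_sr, dtype=float)
        self.lj_sr = np.asarray(self.lj_sr, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if not (len(self.coul_sr) == len(self.lj_sr) == len(self.times)):
            raise ValueError("energy series and times must have equal length")


def _selection_indices(traj: Trajectory, selection) -> np.ndarray:
    if selection is None:
        return np.arange(traj.n_atoms)
    if isinstance(selection, (list, tuple, set)) and selection and isinstance(next(iter(selection)), str):
        idx = traj.select(selection)
    else:
        idx = np.asarray(list(selection), dtype=int)
    if idx.size == 0:
        raise ValueError("atom selection is empty")
    return idx


def traj_rmsd(
    traj: Trajectory,
    ref_frame: int = 0,
    selection: Optional[Sequence] = None,
) -> np.ndarray:
    """Per-frame RMSD (Å) after Kabsch superposition onto the reference frame.

    ``selection`` is a set of atom names (e.g. the backbone) or indices; it
    defines both the fit and the measured atoms.
    """
    idx = _selection_indices(traj, selection)
    ref = traj.frames[ref_frame][idx]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, rmsd = kabsch_superpose(ref, traj.frames[f][idx])
        out[f] = rmsd
    return out


def traj_rmsf(
    traj: Trajectory,
    selection: Optional[Sequence] = None,
    align: bool = False,
    per_atom: bool = False,
):
    """Root-mean-square fluctuation about each atom's mean position.

    Per-atom RMSF is sqrt(mean_f |x_f − <x>|²); residue values average the
    atoms of each residue within the selection.  ``align=True`` first
    superposes every frame onto the mean structure (iterating once), which
    removes global rigid-body drift.  Returns ``(residue_indices, rmsf)``
    arrays, or per-atom values with ``per_atom=True``.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    idx = _selection_indices(traj, selection)
    X = traj.frames[:, idx, :]
    if align:
        mean = X.mean(axis=0)
        aligned = np.empty_like(X)
        for f in range(X.shape[0]):
            R, t, _ = kabsch_superpose(mean, X[f])
            aligned[f] = X[f] @ R.T + t
        X = aligned
        mean = X.mean(axis=0)
    else:
        mean = X.mean(axis=0)
    atom_rmsf = np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))
    if per_atom:
        return idx, atom_rmsf
    res_of = np.array([traj.residue_indices[k] for k in idx])
    res_ids = np.unique(res_of)
    res_rmsf = np.array([atom_rmsf[res_of == r].mean() for r in res_ids])
    return res_ids, res_rmsf


def hbond_counts(
    traj: Trajectory,
    donors: Sequence[int],
    acceptors: Sequence[int],
    crit: HBondCriteria = HBondCriteria(),
    hydrogens: Optional[dict[int, int]] = None,
) -> np.ndarray:
    """Per-frame count of donor–acceptor pairs within the geometric cutoff.

    ``donors``/``acceptors`` are atom indices; a pair with identical donor
    and acceptor atom is never counted.  When an angle cutoff is set,
    ``hydrogens`` must map each donor to its hydrogen atom index and the
    D–H···A angle must be ≥ the cutoff.
    """
    donors = np.asarray(list(donors), dtype=int)
    acceptors = np.asarray(list(acceptors), dtype=int)
    if donors.size == 0 or acceptors.size == 0:
        raise ValueError("donor and acceptor selections must be non-empty")
    if crit.angle_cutoff is not None and hydrogens is None:
        raise ValueError("angle cutoff requires a donor->hydrogen mapping")
    counts = np.zeros(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        D = traj.frames[f][donors]
        A = traj.frames[f][acceptors]
        dist = np.linalg.norm(D[:, None, :] - A[None, :, :], axis=-1)
        ok = dist <= crit.max_donor_acceptor_distance
        same = donors[:, None] == acceptors[None, :]
        ok &= ~same
        if crit.angle_cutoff is not None:
            for di, d_atom in enumerate(donors):
                h = traj.frames[f][hydrogens[int(d_atom)]]
                for ai in range(len(acceptors)):
                    if not ok[di, ai]:
                        continue
                    v1 = traj.frames[f][d_atom] - h
                    v2 = A[ai] - h
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                    if ang < crit.angle_cutoff:
                        ok[di, ai] = False
        counts[f] = int(ok.sum())
    return counts


def energy_summary(series: EnergySeries) -> float:
    """Mean over frames of (Coul-SR + LJ-SR), kJ/mol."""
    if len(series.coul_sr) == 0:
        raise ValueError("energy series is empty")
    return float(np.mean(series.coul_sr + series.lj_sr))


def energy_ratio(e_system: float, e_reference: float) -> float:
    """|E_system| / |E_reference| rounded half-even to 4 decimals.

    Both energies must be nonzero and of the same sign — the ratio compares
    like-for-like interaction strengths.
    """
    if e_reference == 0:
        raise ValueError("reference energy must be nonzero")
    if e_system == 0:
        raise ValueError("system energy must be nonzero")
    if (e_system > 0) != (e_reference > 0):
        raise ValueError("energies must have the same sign")
    return round(abs(e_system) / abs(e_reference), 4)


def read_energy_series(coul_path, lj_path) -> EnergySeries:
    """Read two plain two-column (time, energy) text files into a series.

    Lines starting with '#' or '@' (plotting headers) are ignored.
    """
    def load(path):
        t, v = [], []
        for line in Path(path).read_text().splitlines():
            s = line.strip()
            if not s or s[0] in "#@":
                continue
            parts = s.split()
            t.append(float(parts[0]))
            v.append(float(parts[1]))
        return np.array(t), np.array(v)

    tc, coul = load(coul_path)
    tl, lj = load(lj_path)
    if len(tc) != len(tl) or not np.allclose(tc, tl):
        raise ValueError("Coul-SR and LJ-SR series must share the same time base")
    return EnergySeries(coul, lj, tc)
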