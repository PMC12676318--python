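"""Homology-model QC metrics: template–target sequence identity/coverage
with mismatch listing, and backbone φ/ψ dihedrals for Ramachandran-style
reporting.

The alignment is global but end-gap-free (BLOSUM62, gap open 10 / extend
0.5): a template that covers only an interior stretch of the target — the
typical homology-modeling situation — must not pay for terminal gaps, or
the reported coverage fraction would be distorted.  Identity is matches
over aligned non-gap columns, reported to two decimals.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AlignmentResult",
    "DihedralRecord",
    "global_align",
    "dihedral",
    "phi_psi",
    "backbone_from_pdb",
    "rama_classify",
]

CHAIN_BREAK_CA_DISTANCE = 4.5  # Å


@dataclass(frozen=True)
class AlignmentResult:
    aligned_pairs: tuple[tuple[int, int], ...]  # 1-based (target_pos, template_pos)
    identity: float  # % over aligned non-gap columns, 2 decimals
    coverage: float  # % of target length aligned
    mismatches: tuple[tuple[int, str, str], ...]  # (target pos, target res, template res)
    score: float


@dataclass
class DihedralRecord:
    residue_index: int  # 1-based
    residue_name: str
    phi: Optional[float]  # degrees in (-180, 180]
    psi: Optional[float]
    terminal: bool = False


def global_align(
    target: str,
    template: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """End-gap-free global alignment of two amino-acid sequences."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    if not target or not template:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    # terminal gaps are free: interior coverage must not be penalized
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older PairwiseAligner naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    aln = aligner.align(target, template)[0]

    pairs: list[tuple[int, int]] = []
    for (ts, te), (qs, qe) in zip(aln.aligned[0], aln.aligned[1]):
        for dt in range(te - ts):
            pairs.append((ts + dt + 1, qs + dt + 1))
    matches = 0
    mismatches: list[tuple[int, str, str]] = []
    for tpos, qpos in pairs:
        a, b = target[tpos - 1], template[qpos - 1]
        if a == b:
            matches += 1
        else:
            mismatches.append((tpos, a, b))
    n_cols = len(pairs)
    identity = round(100.0 * matches / n_cols, 2) if n_cols else 0.0
    coverage = round(100.0 * n_cols / len(target), 2)
    return AlignmentResult(
        aligned_pairs=tuple(pairs),
        identity=identity,
        coverage=coverage,
        mismatches=tuple(mismatches),
        score=float(aln.score),
    )


# ---------------------------------------------------------------------------
# dihedrals
# ---------------------------------------------------------------------------

def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (degrees, in (-180, 180]) of four points."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


def backbone_from_pdb(path) -> list[tuple[int, str, dict[str, np.ndarray]]]:
    """Extract per-residue backbone atoms (N, CA, C) from a PDB file."""
    from .io_model import read_trajectory

    traj = read_trajectory(Path(path))
    coords = traj.frames[0]
    residues: dict[int, tuple[str, dict]] = {}
    for k, (name, ridx, rname) in enumerate(
        zip(traj.atom_names, traj.residue_indices, traj.residue_names)
    ):
        if name in ("N", "CA", "C"):
            residues.setdefault(ridx, (rname, {}))[1][name] = coords[k]
    return [(ridx, rn, atoms) for ridx, (rn, atoms) in sorted(residues.items())]


def phi_psi(structure) -> list[DihedralRecord]:
    """Backbone φ/ψ dihedrals for every residue with complete backbone atoms.

    ``structure`` is a PDB path or a list of ``(residue_index, residue_name,
    {atom_name: xyz})`` entries.  φ = C(i−1)–N–CA–C, ψ = N–CA–C–N(i+1).
    Terminal residues lack one angle and are flagged; a CA–CA distance above
    4.5 Å is treated as a chain break.  Residues missing a backbone atom are
    skipped.
    """
    if isinstance(structure, (str, Path)):
        residues = backbone_from_pdb(structure)
    else:
        residues = list(structure)
    complete = [(ridx, rn, at) for ridx, rn, at in residues
                if all(a in at for a in ("N", "CA", "C"))]
    records: list[DihedralRecord] = []
    for pos, (ridx, rname, atoms) in enumerate(complete):
        prev_at = complete[pos - 1][2] if pos > 0 else None
        next_at = complete[pos + 1][2] if pos + 1 < len(complete) else None
        if prev_at is not None:
            if np.linalg.norm(np.asarray(atoms["CA"]) - np.asarray(prev_at["CA"])) > CHAIN_BREAK_CA_DISTANCE:
                prev_at = None
        if next_at is not None:
            if np.linalg.norm(np.asarray(next_at["CA"]) - np.asarray(atoms["CA"])) > CHAIN_BREAK_CA_DISTANCE:
                next_at = None
        phi = dihedral(prev_at["C"], atoms["N"], atoms["CA"], atoms["C"]) if prev_at else None
        psi = dihedral(atoms["N"], atoms["CA"], atoms["C"], next_at["N"]) if next_at else None
        records.append(DihedralRecord(ridx, rname, phi, psi,
                                      terminal=(phi is None or psi is None)))
    return records


# ---------------------------------------------------------------------------
# Ramachandran classification
# ---------------------------------------------------------------------------

def _load_region_map():
    raw = resources.files("hitfunnel.data").joinpath("rama_map.json").read_text()
    return json.loads(raw)


def rama_classify(records: Sequence[DihedralRecord], region_map=None):
    """Label residues favored / allowed / outlier by coarse φ/ψ regions.

    The bundled region map is a coarse polygonal approximation (α, β and
    left-handed-α basins), not any particular server's criterion.  Points on
    a polygon edge take the more favorable class.  Residues lacking either
    angle are unclassifiable and excluded from the percentages.
    """
    from shapely.geometry import Point, Polygon

    if region_map is None:
        region_map = _load_region_map()
    favored = [Polygon(p) for p in region_map["favored"]]
    allowed = [Polygon(p) for p in region_map["allowed"]]
    counts = {"favored": 0, "allowed": 0, "outlier": 0}
    labels: dict[int, str] = {}
    for rec in records:
        if rec.phi is None or rec.psi is None:
            continue
        pt = Point(rec.phi, rec.psi)
        if any(poly.covers(pt) for poly in favored):
            lab = "favored"
        elif any(poly.covers(pt) for poly in allowed):
            lab = "allowed"
        else:
            lab = "outlier"
        counts[lab] += 1
        labels[rec.residue_index] = lab
    total = sum(counts.values())
    pct = {k: (100.0 * v / total if total else 0.0) for k, v in counts.items()}
    return {"counts": counts, "percent": pct, "labels": labels}
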